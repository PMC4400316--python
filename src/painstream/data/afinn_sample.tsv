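abandoned	-2
ache	-2
aching	-2
admire	3
adorable	3
afraid	-2
aggressive	-2
agony	-3
alive	1
alone	-2
amazing	4
angry	-3
annoyed	-2
anxious	-2
appreciate	2
ashamed	-2
awesome	4
awful	-3
bad	-3
beautiful	3
best	3
better	2
bitter	-2
bless	2
blessed	3
bored	-2
brave	2
brilliant	4
broken	-1
calm	2
care	2
celebrate	3
charming	3
cheerful	2
comfort	2
cool	1
crap	-3
crazy	-2
cried	-2
cries	-2
cry	-1
crying	-2
cute	2
damn	-4
dead	-3
delight	3
depressed	-2
despair	-3
destroyed	-3
devastated	-2
die	-3
dies	-3
dirty	-2
disappointed	-2
disaster	-2
disgusting	-3
distressed	-2
dread	-2
dying	-3
eager	2
ecstatic	4
embarrassed	-2
enjoy	2
enjoyed	2
evil	-3
excellent	3
excited	3
exciting	3
fabulous	4
fail	-2
failed	-2
fantastic	4
fear	-2
fearful	-2
fine	2
fun	4
funny	4
glad	3
gloomy	-2
good	3
gorgeous	3
grateful	3
great	3
grief	-2
happiness	3
happy	3
hate	-3
hated	-3
hates	-3
heartbroken	-3
hell	-4
helpless	-2
hope	2
hopeful	2
hopeless	-2
horrible	-3
hug	2
hurt	-2
hurting	-2
hurts	-2
ill	-2
injured	-2
injury	-2
inspired	2
joy	3
joyful	3
kind	2
laugh	2
laughing	2
lol	3
lonely	-2
lose	-3
losing	-3
lost	-3
love	3
loved	3
lovely	3
loves	3
lucky	3
mad	-3
miserable	-3
miss	-2
missed	-2
nervous	-2
nice	3
numb	-1
pain	-2
painful	-2
pains	-2
paradise	3
peace	2
perfect	3
pleasure	3
poor	-2
proud	2
regret	-2
relaxed	2
relief	1
relieved	2
sad	-2
sadly	-2
scared	-2
scary	-2
sick	-2
smile	2
smiling	2
sob	-2
sobbing	-2
sore	-1
sorrow	-2
sorry	-1
strong	2
struggle	-2
struggling	-2
stupid	-2
suffer	-2
suffering	-2
super	3
sweet	2
terrible	-3
terrified	-3
thankful	2
thrilled	5
tired	-2
tragic	-2
ugly	-3
unbearable	-2
upset	-2
weak	-2
weary	-2
welcome	2
win	4
winner	4
wonderful	4
worry	-3
worried	-3
worse	-3
worst	-3
wow	4
yay	3
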