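:)	2
:-)	2
:]	2
=)	2
:D	3
:-D	3
xD	3
XD	3
;)	2
;-)	2
:P	1
:p	1
:(	-2
:-(	-2
:[	-2
=(	-2
:'(	-3
;(	-2
D:	-3
:/	-1
:-/	-1
:|	-1
>:(	-3
<3	3
\o/	3
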