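"""Run the whole pipeline (simulate -> content -> sentiment -> geo -> network).

Equivalent to `painstream run-all --seed 11 --out painstream_out`; every
number in the printed summary is re-derivable by calling the module functions
directly.
"""

import json

from painstream import RunConfig, run_pipeline
from painstream.synth import GeneratorConfig, NetworkConfig

cfg = RunConfig(
    seed=11,
    out_dir="scratch/example_out",
    k_features=50,
    generator=GeneratorConfig(
        n_tweets=800,
        network=NetworkConfig(topology="planted_partition", n_users=80,
                              n_blocks=8, p_in=0.3, p_out=0.01),
    ),
)
summary = run_pipeline(cfg)
print(json.dumps(summary, indent=1, sort_keys=True))
print(f"\nreport bundle written under {cfg.out_dir}/")
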