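"""The train-fraction sweep protocol on a scaled-down dataset.

Mirrors the study protocol -- stratified splits at several training
fractions, replicated, raw and fuzzy arms paired -- at reduced size
(2 fractions x 2 replicates, 150 samples) so it runs in a few minutes.
The full 1080-sample benchmark is what scripts/acceptance.py executes.
"""

from tennisgcn import GeneratorConfig, SweepSpec, compare_variants, run_sweep
from tennisgcn.model import TrainConfig

spec = SweepSpec(
    fractions=(0.45, 0.65),
    replicates=2,
    base_seed=1,
    train_cfg=TrainConfig(learning_rate=0.02, batch_size=32, max_epochs=80,
                          patience=8, warmup_epochs=5),
)
result = run_sweep(spec, gen_cfg=GeneratorConfig(class_counts=(50, 50, 50), seed=1))

for variant in ("raw", "fuzzy"):
    print(f"\n{variant} variant (means over replicates):")
    print(result.accuracy_table(variant).round(3).to_string())

diff = compare_variants(result)
print("\npaired fuzzy - raw differences per fraction:")
print(diff.round(3).to_string())
print("\nA positive accuracy_diff means the fuzzified input helped on that split size.")
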