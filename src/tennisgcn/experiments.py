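"""Train-fraction sweep protocol and the fuzzy-vs-raw paired comparison.

The evaluation protocol mirrors the study: the 1080-sample dataset is split
at training fractions from 10% to 65% in 5% steps, three independent
replicates per fraction, and both network variants -- raw 2-channel
coordinates and 6-channel fuzzified input -- are run on *identical* splits
and initialization seeds (a paired design), so their accuracy difference is
not confounded by split luck.  The fuzzy membership bank is refit on each
replicate's training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import feature_matrix
from .fuzzy import fit_bank, fuzzify_array
from .model import ModelConfig, TrainConfig, build_model, evaluate, train
from .skeleton_io import CLASSES
from .stgraph import canonical_graph
from .synth import GeneratorConfig, SyntheticDataset, generate_dataset, samples_to_array

__all__ = [
    "SweepSpec",
    "ExperimentResult",
    "stratified_split",
    "run_single",
    "run_sweep",
    "compare_variants",
]

DEFAULT_FRACTIONS = tuple(round(0.10 + 0.05 * i, 2) for i in range(12))  # 10%..65%


@dataclass(frozen=True)
class SweepSpec:
    """Sweep protocol parameters.

    ``train_cfg`` applies to every run; the default is sized for the
    benchmark (see docs/methods.md for the problem sizes used).
    """

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    replicates: int = 3
    variants: tuple[str, ...] = ("raw", "fuzzy")
    base_seed: int = 0
    train_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=0.02, momentum=0.9, batch_size=32,
        max_epochs=60, tol=1e-4, patience=6, warmup_epochs=5,
    ))

    def __post_init__(self) -> None:
        if not all(0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.variants) - {"raw", "fuzzy"}
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}")


@dataclass
class ExperimentResult:
    """Per-run records plus the generator/sweep configuration echo."""

    records: list[dict]
    spec: SweepSpec
    generator: GeneratorConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {k: v for k, v in r.items() if k not in ("confusion", "tp_rates")}
            if r.get("tp_rates") is not None:
                for ci, cname in enumerate(CLASSES):
                    row[f"tp_{cname}"] = r["tp_rates"][ci]
            rows.append(row)
        return pd.DataFrame(rows)

    def accuracy_table(self, variant: str) -> pd.DataFrame:
        """Mean per-class true-positive rates and accuracy by fraction
        (the shape of the study's per-network result tables)."""
        df = self.to_dataframe()
        df = df[(df["variant"] == variant) & df["accuracy"].notna()]
        cols = [f"tp_{c}" for c in CLASSES] + ["accuracy", "epochs_run"]
        return df.groupby("fraction")[cols].mean()


def stratified_split(labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified random split into (train indices, test indices).

    Per-class train counts are ``round(fraction * n_class)``; the split is
    disjoint and exhaustive.  Raises ``ValueError`` if any class would end
    up empty on either side.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_train = int(round(fraction * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValueError(
                f"fraction {fraction} leaves class {c} empty on one side "
                f"(class size {len(idx)}, train {n_train})"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _standardize(F: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    mean = F[train_idx].mean(axis=0)
    sd = F[train_idx].std(axis=0)
    return (F - mean) / np.maximum(sd, 1e-8)


def run_single(
    dataset: SyntheticDataset,
    fraction: float,
    variant: str = "raw",
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    use_active_features: bool = True,
) -> dict:
    """One split + fit + test-set evaluation; returns a result record."""
    spec = SweepSpec(fractions=(fraction,), replicates=1, variants=(variant,),
                     base_seed=seed, **({} if train_cfg is None else {"train_cfg": train_cfg}))
    result = run_sweep(spec, dataset=dataset, use_active_features=use_active_features)
    return result.records[0]


def run_sweep(
    spec: SweepSpec,
    gen_cfg: GeneratorConfig | None = None,
    dataset: SyntheticDataset | None = None,
    use_active_features: bool = True,
) -> ExperimentResult:
    """Run the full fraction x replicate x variant protocol.

    The dataset is generated once (or passed in); raw and fuzzy arms of each
    (fraction, replicate) cell share the split and the model/training seeds.
    Training failures are recorded on the run record and the sweep continues.
    """
    if dataset is None:
        gen_cfg = gen_cfg or GeneratorConfig()
        dataset = generate_dataset(gen_cfg)
    else:
        gen_cfg = dataset.config
    graph = canonical_graph()
    X = samples_to_array(dataset.samples)
    y = dataset.labels
    F_all = feature_matrix(dataset.samples).astype(np.float32)
    n_feats = F_all.shape[1]

    records: list[dict] = []
    for fraction in spec.fractions:
        for rep in range(spec.replicates):
            cell_seed = int(
                np.random.SeedSequence([spec.base_seed, int(round(fraction * 100)), rep])
                .generate_state(1)[0] % (2**31)
            )
            split_rng = np.random.default_rng(cell_seed)
            train_idx, test_idx = stratified_split(y, fraction, split_rng)
            F = _standardize(F_all, train_idx) if use_active_features else None
            for variant in spec.variants:
                rec = {
                    "variant": variant, "fraction": fraction, "replicate": rep,
                    "seed": cell_seed, "n_train": len(train_idx), "n_test": len(test_idx),
                }
                try:
                    if variant == "fuzzy":
                        bank = fit_bank([dataset.samples[i] for i in train_idx])
                        Xv = fuzzify_array(X.transpose(1, 0, 2, 3), bank).transpose(1, 0, 2, 3)
                        Xv = Xv.astype(np.float32)
                    else:
                        Xv = X
                    mcfg = ModelConfig(
                        input_channels=Xv.shape[1],
                        use_active_features=use_active_features,
                        n_feature_inputs=n_feats if use_active_features else 0,
                    )
                    model = build_model(mcfg, graph, seed=cell_seed)
                    tcfg = replace(spec.train_cfg, seed=cell_seed)
                    fit = train(model, X[train_idx] if variant == "raw" else Xv[train_idx],
                                y[train_idx],
                                None if F is None else F[train_idx], tcfg)
                    ev = evaluate(model, Xv[test_idx], y[test_idx],
                                  None if F is None else F[test_idx])
                    rec.update(
                        accuracy=ev.accuracy, tp_rates=ev.tp_rates,
                        confusion=ev.confusion, epochs_run=fit.epochs_run,
                    )
                except (ValueError, RuntimeError) as exc:  # annotate, keep sweeping
                    rec.update(accuracy=np.nan, tp_rates=None, confusion=None,
                               epochs_run=None, error=str(exc))
                records.append(rec)
    return ExperimentResult(records=records, spec=spec, generator=gen_cfg)


def compare_variants(result: ExperimentResult) -> pd.DataFrame:
    """Per-fraction paired differences (fuzzy - raw) in accuracy and epochs.

    Requires both arms at matched (fraction, replicate) cells; raises
    ``ValueError`` if an arm is missing.
    """
    df = result.to_dataframe()
    for v in ("raw", "fuzzy"):
        if v not in set(df["variant"]):
            raise ValueError(f"missing {v} arm; cannot form paired differences")
    keys = ["fraction", "replicate"]
    raw = df[df["variant"] == "raw"].set_index(keys)
    fuzzy = df[df["variant"] == "fuzzy"].set_index(keys)
    if not raw.index.equals(fuzzy.index):
        raise ValueError("raw and fuzzy arms are not matched on (fraction, replicate)")
    paired = pd.DataFrame({
        "accuracy_diff": fuzzy["accuracy"] - raw["accuracy"],
        "epochs_diff": fuzzy["epochs_run"] - raw["epochs_run"],
    }).reset_index()
    out = paired.groupby("fraction")[["accuracy_diff", "epochs_diff"]].mean()
    out["accuracy_diff_sign"] = np.sign(out["accuracy_diff"]).astype(int)
    return out
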