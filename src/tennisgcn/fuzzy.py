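"""Trapezoidal fuzzification of node-attribute channels.

Each coordinate channel of a motion sample is mapped to three overlapping
fuzzy sets -- *low*, *mid*, *high* -- with piecewise-linear trapezoidal
membership functions bounded in [0, 1]:

    mu_low(x)  = 1 for x < c,   (d - x)/(d - c) on [c, d],   0 for x > d
    mu_mid(x)  = 0 outside [a, d], rising on [a, b], 1 on (b, c), falling on [c, d]
    mu_high(x) = 0 for x < a,   (x - a)/(b - a) on [a, b],   1 for x > b

with breakpoints a < b <= c < d.  When the low ramp [c, d] coincides with the
mid rise [a, b] and the mid fall [c, d] with the high rise [a, b], the three
memberships form a partition of unity: they sum to one at every x, so
fuzzification re-encodes a value without losing mass.  Breakpoints are fitted
as empirical quantiles of the training split only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .skeleton_io import MotionSample

__all__ = [
    "TrapezoidParams",
    "FuzzyBank",
    "mu_low",
    "mu_mid",
    "mu_high",
    "fit_bank",
    "fuzzify_sample",
    "fuzzify_array",
]


@dataclass(frozen=True)
class TrapezoidParams:
    """Breakpoints a < b <= c < d of one trapezoidal membership function.

    The low-shoulder function uses only (c, d) -- its a and b default to
    -inf -- and the high-shoulder function uses only (a, b), with c and d at
    +inf.
    """

    a: float = -math.inf
    b: float = -math.inf
    c: float = math.inf
    d: float = math.inf

    def __post_init__(self) -> None:
        finite = [v for v in (self.a, self.b, self.c, self.d) if math.isfinite(v)]
        if any(x >= y for x, y in zip(finite, finite[1:])):
            raise ValueError(f"breakpoints must be strictly increasing, got {self}")


def mu_low(x, p: TrapezoidParams):
    """Low-shoulder membership: 1 below c, falling ramp on [c, d], 0 above d."""
    if not p.c < p.d:
        raise ValueError(f"mu_low needs c < d, got c={p.c}, d={p.d}")
    x = np.asarray(x, dtype=float)
    out = np.clip((p.d - x) / (p.d - p.c), 0.0, 1.0)
    return out if out.ndim else float(out)


def mu_mid(x, p: TrapezoidParams):
    """Core trapezoid: rises on [a, b], plateau at 1 on (b, c), falls on [c, d]."""
    if not (p.a < p.b <= p.c < p.d):
        raise ValueError(f"mu_mid needs a < b <= c < d, got {p}")
    x = np.asarray(x, dtype=float)
    rise = (x - p.a) / (p.b - p.a)
    fall = (p.d - x) / (p.d - p.c)
    out = np.clip(np.minimum(rise, fall), 0.0, 1.0)
    return out if out.ndim else float(out)


def mu_high(x, p: TrapezoidParams):
    """High-shoulder membership: 0 below a, rising ramp on [a, b], 1 above b."""
    if not p.a < p.b:
        raise ValueError(f"mu_high needs a < b, got a={p.a}, b={p.b}")
    x = np.asarray(x, dtype=float)
    out = np.clip((x - p.a) / (p.b - p.a), 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FuzzyBank:
    """Per-channel (low, mid, high) trapezoid triple.

    The triples are coupled so the three memberships of each channel form a
    partition of unity (see module docstring).
    """

    channels: tuple[tuple[TrapezoidParams, TrapezoidParams, TrapezoidParams], ...]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def memberships(self, x: np.ndarray, channel: int) -> np.ndarray:
        """Stack (low, mid, high) memberships of ``x`` for one channel."""
        lo, mid, hi = self.channels[channel]
        return np.stack([mu_low(x, lo), mu_mid(x, mid), mu_high(x, hi)])

    def to_yaml(self) -> str:
        doc = {
            f"channel_{i}": {"a": m.a, "b": m.b, "c": m.c, "d": m.d}
            for i, (_, m, _) in enumerate(self.channels)
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FuzzyBank":
        doc = yaml.safe_load(text)
        chans = []
        for i in range(len(doc)):
            p = doc[f"channel_{i}"]
            chans.append(_coupled_triple(p["a"], p["b"], p["c"], p["d"]))
        return cls(channels=tuple(chans))


def _coupled_triple(a: float, b: float, c: float, d: float):
    """Low/mid/high triple sharing ramps so memberships sum to one."""
    mid = TrapezoidParams(a, b, c, d)
    low = TrapezoidParams(c=a, d=b)      # low falls where mid rises
    high = TrapezoidParams(a=c, b=d)     # high rises where mid falls
    return (low, mid, high)


def fit_bank(
    samples,
    coverage: tuple[float, float] = (0.10, 0.90),
    inner: tuple[float, float] = (0.35, 0.65),
) -> FuzzyBank:
    """Fit per-channel trapezoid breakpoints at data quantiles.

    The mid trapezoid's (a, b, c, d) are placed at the ``coverage[0]``,
    ``inner[0]``, ``inner[1]`` and ``coverage[1]`` quantiles of the pooled
    channel values across all samples, nodes and frames; low and high share
    its ramps, giving a partition of unity over the whole real line.

    Raises ``ValueError`` on an empty collection or a channel with (near-)zero
    spread, for which no non-degenerate trapezoid exists.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot fit a fuzzy bank on an empty dataset")
    if not 0.0 <= coverage[0] < inner[0] < inner[1] < coverage[1] <= 1.0:
        raise ValueError(f"quantile anchors must be ordered, got {coverage}, {inner}")
    data = np.concatenate([np.asarray(s.data).reshape(s.data.shape[0], -1) for s in samples], axis=1)
    qs = (coverage[0], inner[0], inner[1], coverage[1])
    chans = []
    for ci in range(data.shape[0]):
        a, b, c, d = np.quantile(data[ci], qs)
        if not (a < b <= c < d):
            raise ValueError(
                f"channel {ci} is degenerate (quantiles {a}, {b}, {c}, {d}); "
                "constant or near-constant channels cannot be fuzzified"
            )
        chans.append(_coupled_triple(float(a), float(b), float(c), float(d)))
    return FuzzyBank(channels=tuple(chans))


def fuzzify_array(data: np.ndarray, bank: FuzzyBank) -> np.ndarray:
    """Fuzzify a (C, ...) array into (3*C, ...) membership channels.

    Output channel order is (low_0, mid_0, high_0, low_1, mid_1, high_1, ...).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] != bank.n_channels:
        raise ValueError(
            f"sample has {data.shape[0]} channels but bank expects {bank.n_channels}"
        )
    return np.concatenate([bank.memberships(data[c], c) for c in range(data.shape[0])])


def fuzzify_sample(s: MotionSample, bank: FuzzyBank) -> MotionSample:
    """Replace each coordinate channel by its three membership channels.

    C grows from 2 to 6 by default; V and T are unchanged and every output
    value lies in [0, 1].
    """
    fuzzy = fuzzify_array(s.data, bank)
    names = tuple(
        f"{base}_{level}" for base in s.channel_names for level in ("low", "mid", "high")
    )
    return replace(s, data=fuzzy, channel_names=names)
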