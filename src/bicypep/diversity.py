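"""Rarefaction curves and saturation-model diversity estimation.

Plotting the number of distinct peptide sequences against the number of
reads analyzed yields a saturation curve.  For an error-free sample of a
finite population it approaches an asymptote and is modeled as

    y = a * (1 - exp(-x / k))                      (saturating model)

where ``a`` is the total number of distinct sequences in the sampled
population and ``k`` is a constant set by the abundance distribution.  Real
sequencing data do not saturate: each erroneous read tends to create a novel
sequence, adding a linear term

    y = a * (1 - exp(-x / k)) + b * x              (saturating + error model)

where ``b`` is the average per-read error rate — the fraction of reads
carrying an error that produces a novel sequence.  Fitting the second model
before and after abundance-based error correction estimates both the true
diversity and how much of the apparent diversity was sequencing noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from bicypep.preprocess import AbundanceTable, denoise_counts

__all__ = [
    "RarefactionCurve",
    "SaturationFit",
    "rarefaction_curve",
    "fit_saturation",
    "diversity_report",
]


@dataclass
class RarefactionCurve:
    """Mean distinct-sequence counts at increasing numbers of sampled reads."""

    xs: np.ndarray
    ys: np.ndarray
    y_sd: np.ndarray
    repeats: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.y_sd = np.asarray(self.y_sd, dtype=float)
        if np.any(np.diff(self.xs) <= 0):
            raise ValueError("xs must be strictly increasing")
        if np.any(self.ys < 0) or np.any(np.diff(self.ys) < 0):
            raise ValueError("ys must be non-negative and non-decreasing")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"x": self.xs.astype(int), "y_mean": self.ys, "y_sd": self.y_sd}
        ).to_csv(path, index=False)


@dataclass
class SaturationFit:
    """Fitted saturation-model parameters with diagnostics."""

    model: str  # "eq1" (saturating) or "eq2" (saturating + error)
    a: float
    k: float
    b: float
    rss: float
    converged: bool

    def predict(self, xs: Sequence[float]) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        return self.a * (1.0 - np.exp(-xs / self.k)) + self.b * xs

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "a": self.a,
            "k": self.k,
            "b": self.b,
            "rss": self.rss,
            "converged": self.converged,
        }


def _distinct_prefix_counts(codes: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Distinct-count among the first x elements, for each x, in O(n log n)."""
    n = len(codes)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    first_in_group = np.empty(n, dtype=bool)
    first_in_group[0] = True
    first_in_group[1:] = sorted_codes[1:] != sorted_codes[:-1]
    is_first = np.zeros(n, dtype=np.int64)
    is_first[order[first_in_group]] = 1
    cum = np.cumsum(is_first)
    return cum[xs - 1]


def rarefaction_curve(
    peptide_stream: Sequence[str],
    n_points: int = 50,
    repeats: int = 10,
    seed: Optional[int] = None,
) -> RarefactionCurve:
    """Rarefaction by random subsampling without replacement.

    The per-read sequence stream is permuted ``repeats`` times (seeded) and
    the number of distinct sequences among the first x reads is averaged at
    ``n_points`` evenly spaced depths up to the stream length.  Permutation
    makes the curve independent of read order in the input file, which
    reflects chip geometry rather than the sample.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    stream = list(peptide_stream)
    if not stream:
        raise ValueError("empty peptide stream")
    n = len(stream)
    codes = pd.factorize(np.asarray(stream, dtype=object))[0]
    xs = np.unique(np.linspace(1, n, num=min(n_points, n)).round().astype(int))
    rng = np.random.default_rng(seed)
    ys = np.empty((repeats, len(xs)), dtype=float)
    for r in range(repeats):
        perm = rng.permutation(n)
        ys[r] = _distinct_prefix_counts(codes[perm], xs)
    return RarefactionCurve(
        xs=xs.astype(float),
        ys=ys.mean(axis=0),
        y_sd=ys.std(axis=0, ddof=0),
        repeats=repeats,
        seed=seed,
    )


def _eq1(x, a, k):
    return a * (1.0 - np.exp(-x / k))


def _eq2(x, a, k, b):
    return a * (1.0 - np.exp(-x / k)) + b * x


def fit_saturation(curve: RarefactionCurve, model: str = "eq2") -> SaturationFit:
    """Nonlinear least-squares fit of the saturation model to a curve.

    Initialization: a0 = max(y); k0 = first x where y exceeds a0(1 - 1/e);
    for the error model, b0 = slope over the last 20% of points.  Bounds:
    a in (0, 2*max(y)], k > 0, b in [0, 1].  A failed fit returns
    ``converged=False`` with NaN parameters rather than raising.
    """
    if model not in ("eq1", "eq2"):
        raise ValueError(f"unknown model {model!r}")
    xs, ys = curve.xs, curve.ys
    min_points = 3 if model == "eq1" else 4
    if len(xs) < min_points:
        raise ValueError(f"{model} needs at least {min_points} curve points")
    ymax = float(ys.max())
    failed = SaturationFit(model, float("nan"), float("nan"),
                           float("nan") if model == "eq2" else 0.0,
                           float("nan"), False)
    if ymax <= 0:
        return failed
    a0 = ymax
    above = np.nonzero(ys >= a0 * (1.0 - np.exp(-1.0)))[0]
    k0 = float(xs[above[0]]) if len(above) else float(xs[-1])
    if model == "eq1":
        p0, bounds, func = [a0, k0], ([1e-12, 1e-12], [2 * ymax, np.inf]), _eq1
    else:
        tail = max(2, int(np.ceil(0.2 * len(xs))))
        b0 = float(np.polyfit(xs[-tail:], ys[-tail:], 1)[0])
        b0 = min(max(b0, 0.0), 1.0)
        # the linear term competes with the asymptote; start a below max(y)
        a0 = max(a0 - b0 * float(xs[-1]), 1.0)
        p0 = [a0, k0, b0]
        bounds = ([1e-12, 1e-12, 0.0], [2 * ymax, np.inf, 1.0])
        func = _eq2
    try:
        popt, _ = curve_fit(func, xs, ys, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return failed
    rss = float(np.sum((func(xs, *popt) - ys) ** 2))
    if model == "eq1":
        a, k = popt
        b = 0.0
    else:
        a, k, b = popt
    if not np.isfinite([a, k, b]).all() or a <= 0 or k <= 0:
        return failed
    return SaturationFit(model, float(a), float(k), float(b), rss, True)


def diversity_report(
    table_before: AbundanceTable,
    table_after: Optional[AbundanceTable],
    read_stream: Sequence[str],
    seed: Optional[int] = None,
    n_points: int = 50,
    repeats: int = 10,
    max_mismatch: int = 2,
    min_ratio: float = 10.0,
) -> dict:
    """Saturation fits before and after error correction on the same reads.

    ``read_stream`` holds one nucleotide sequence per read (the sequences
    pooled in ``table_before``).  The post-correction stream is obtained by
    mapping each read to its corrected representative, re-deriving the merge
    map from ``table_before`` with the given correction parameters; when
    ``table_after`` is provided it is checked for consistency.
    """
    merged, parent_map = denoise_counts(
        table_before.nt_counts(), max_mismatch, min_ratio
    )
    if table_after is not None and table_after.nt_counts() != merged:
        raise ValueError(
            "table_after does not match correction of table_before under "
            "the given parameters"
        )
    stream_after = [parent_map.get(s, s) for s in read_stream]
    curve_before = rarefaction_curve(read_stream, n_points, repeats, seed)
    curve_after = rarefaction_curve(stream_after, n_points, repeats, seed)
    fit_before = fit_saturation(curve_before, "eq2")
    fit_after = fit_saturation(curve_after, "eq2")
    return {
        "before": fit_before.to_dict(),
        "after": fit_after.to_dict(),
        "b_reduction": fit_before.b - fit_after.b,
        "seed": seed,
        "curve_before": curve_before,
        "curve_after": curve_after,
    }
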