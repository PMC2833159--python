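"""Binding-feature threshold optimization by Enrichment x Coverage.

Per-feature coverage curves are computed over the verified and the predicted
hit sets while relaxing one threshold at a time; candidate threshold values
are the four or five with the largest verified-minus-predicted coverage gap
(500 combinations with the default 5,5,5,4 grid).  The Cartesian grid is then
scored and the combination with the maximum EC value -- unrounded enrichment
times coverage in percent -- wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from orthomir.features import FEATURE_NAMES, SCAN_MAXIMA, FilterParams
from orthomir.stats import enrichment

DEFAULT_GRID_SHAPE = (5, 5, 5, 4)


@dataclass(frozen=True)
class CoverageCurve:
    feature_name: str
    values: tuple[int, ...]
    cov_verified: tuple[float, ...]
    cov_predicted: tuple[float, ...]

    @property
    def gap(self) -> tuple[float, ...]:
        return tuple(v - p for v, p in zip(self.cov_verified, self.cov_predicted))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_name,
                "threshold": self.values,
                "cov_verified": self.cov_verified,
                "cov_predicted": self.cov_predicted,
                "gap": self.gap,
            }
        )


@dataclass(frozen=True)
class GridPoint:
    params: FilterParams
    n_pred_kept: int
    n_ver_kept: int
    coverage_pct: float
    enrichment: float
    ec: float


def _feature_matrix(hits: pd.DataFrame | Sequence, feature_name: str) -> np.ndarray:
    if isinstance(hits, pd.DataFrame):
        return hits[feature_name].to_numpy()
    return np.array([getattr(h, feature_name) for h in hits])


def coverage_curve(
    hits: pd.DataFrame,
    verified_flags: Sequence[bool],
    feature_name: str,
    value_range: Sequence[int] | None = None,
) -> CoverageCurve:
    """Fraction of each set kept at each (inclusive) threshold value.

    ``hits`` is a table with one row per predicted pair carrying the four
    feature columns; ``verified_flags`` marks the experimentally verified
    subset.  The predicted coverage is over all rows.
    """
    flags = np.asarray(verified_flags, dtype=bool)
    if len(flags) != len(hits):
        raise ValueError("verified_flags length must match hits")
    if not flags.any():
        raise ValueError("no verified hits; coverage optimization undefined")
    if value_range is None:
        value_range = range(SCAN_MAXIMA[FEATURE_NAMES.index(feature_name)] + 1)
    values = tuple(int(v) for v in value_range)
    feat = _feature_matrix(hits, feature_name)
    cov_v = tuple(float((feat[flags] <= v).mean()) for v in values)
    cov_p = tuple(float((feat <= v).mean()) for v in values)
    return CoverageCurve(feature_name, values, cov_v, cov_p)


def select_ranges(
    curves: Mapping[str, CoverageCurve] | Sequence[CoverageCurve],
    k_per_feature: Sequence[int] = DEFAULT_GRID_SHAPE,
) -> dict[str, list[int]]:
    """Per feature, the k threshold values with the largest coverage gap.

    Ties break toward stricter (smaller) values; the result is ascending.
    """
    if not isinstance(curves, Mapping):
        curves = {c.feature_name: c for c in curves}
    out: dict[str, list[int]] = {}
    for name, k in zip(FEATURE_NAMES, k_per_feature):
        curve = curves[name]
        if k > len(curve.values):
            raise ValueError(f"k={k} exceeds the {len(curve.values)} scanned values of {name}")
        ranked = sorted(zip(curve.gap, curve.values), key=lambda t: (-t[0], t[1]))
        out[name] = sorted(v for _, v in ranked[:k])
    return out


def grid_search(
    hits: pd.DataFrame,
    verified_flags: Sequence[bool],
    candidate_ranges: Mapping[str, Sequence[int]],
    totals: tuple[int, int] | None = None,
) -> tuple[list[GridPoint], GridPoint]:
    """Score every threshold combination; the maximum EC value wins.

    ``totals`` is ``(n_ver_total, n_pred_total)`` -- the baseline denominators
    for coverage and enrichment (default: the verified and predicted rows of
    ``hits`` themselves, i.e. the step-1 output sets).  Ties break by higher
    coverage, then by stricter parameters in field order.
    """
    flags = np.asarray(verified_flags, dtype=bool)
    feats = {name: _feature_matrix(hits, name) for name in FEATURE_NAMES}
    n_ver_total, n_pred_total = totals if totals is not None else (int(flags.sum()), len(flags))
    if n_ver_total <= 0 or n_pred_total <= 0:
        raise ValueError("baseline totals must be positive")
    points: list[GridPoint] = []
    combos = itertools.product(*(candidate_ranges[name] for name in FEATURE_NAMES))
    for combo in combos:
        keep = np.ones(len(flags), dtype=bool)
        for name, vmax in zip(FEATURE_NAMES, combo):
            keep &= feats[name] <= vmax
        n_pred_kept = int(keep.sum())
        n_ver_kept = int((keep & flags).sum())
        res = enrichment(n_ver_kept, n_ver_total, n_pred_kept, n_pred_total)
        coverage_pct = res.ratio_ver_pct
        ec = res.enrichment * coverage_pct
        points.append(
            GridPoint(
                params=FilterParams(*combo),
                n_pred_kept=n_pred_kept,
                n_ver_kept=n_ver_kept,
                coverage_pct=coverage_pct,
                enrichment=res.enrichment,
                ec=ec,
            )
        )
    best = max(points, key=lambda p: (p.ec, p.coverage_pct, tuple(-v for v in p.params.as_tuple())))
    return points, best


def grid_to_frame(points: Sequence[GridPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "max_mm_mrna": [p.params.max_mm_mrna for p in points],
            "max_mm_mirna": [p.params.max_mm_mirna for p in points],
            "max_gu_whole": [p.params.max_gu_whole for p in points],
            "max_gu_seed": [p.params.max_gu_seed for p in points],
            "n_pred_kept": [p.n_pred_kept for p in points],
            "n_ver_kept": [p.n_ver_kept for p in points],
            "coverage_pct": [p.coverage_pct for p in points],
            "enrichment": [p.enrichment for p in points],
            "ec": [p.ec for p in points],
        }
    )


def plot_curves(curves, path) -> None:
    """Diagnostic coverage-curve figure (one panel per feature)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(curves, Mapping):
        curves = {c.feature_name: c for c in curves}
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, name in zip(axes.ravel(), FEATURE_NAMES):
        c = curves[name]
        ax.plot(c.values, c.cov_verified, label="verified", color="tab:orange")
        ax.plot(c.values, c.cov_predicted, label="predicted", color="tab:blue")
        ax.bar(c.values, c.gap, alpha=0.3, color="gold", label="gap")
        ax.set_title(name)
        ax.set_xlabel("threshold")
        ax.set_ylabel("coverage")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_grid(points: Sequence[GridPoint], best: GridPoint, path) -> None:
    """Enrichment vs coverage scatter of all grid combinations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter([p.enrichment for p in points], [p.coverage_pct for p in points], s=12, alpha=0.5)
    ax.scatter([best.enrichment], [best.coverage_pct], s=60, color="black", zorder=3, label="max EC")
    ax.set_xlabel("Enrichment (fold)")
    ax.set_ylabel("Coverage of verified pairs (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
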