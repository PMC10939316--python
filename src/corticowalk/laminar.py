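"""Laminar-position quantification of marked neurons.

Each neuron's relative radial depth is d1 / (d1 + d2), where d1 and d2 are
the shortest distances to the ventricular and pial boundary polylines.
Depths are binned into equal zones and genotype distributions are compared
with an arcsin(sqrt(p)) transform, a two-way ANOVA and Tukey contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoundaryPolyline",
    "NeuronMark",
    "ZoneDistribution",
    "shortest_distance_to_polyline",
    "relative_distance",
    "bin_into_zones",
    "arcsin_sqrt",
    "compare_distributions",
]


@dataclass(frozen=True)
class BoundaryPolyline:
    """An ordered open polyline (um) tracing a tissue boundary."""

    vertices: np.ndarray  # (M, 2)
    role: str  # "ventricular" | "pial"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("polyline needs >= 2 two-dimensional vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("polyline vertices must be finite")
        if self.role not in ("ventricular", "pial"):
            raise ValueError(f"unknown boundary role {self.role!r}")


@dataclass(frozen=True)
class NeuronMark:
    x: float
    y: float
    marker: str = "green"  # green | red
    genotype: str = "control"
    animal_id: str = "a0"
    hemisphere_id: str = "h0"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("mark coordinates must be finite")


@dataclass
class ZoneDistribution:
    """Counts per zone, plus derived fractions, for one group of marks.

    ``counts[k]`` is zone k in the *ventricular-first* convention (zone 0
    touches the ventricle).  ``zone_labels_pial_first`` gives the matching
    figure-style numbering with zone 1 at the pia.
    """

    counts: np.ndarray
    n_zones: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n_zones,):
            raise ValueError("counts length must equal n_zones")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def fractions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.full(self.n_zones, np.nan)
        return self.counts / total

    @property
    def zone_labels_ventricular_first(self) -> list[int]:
        return list(range(1, self.n_zones + 1))

    @property
    def zone_labels_pial_first(self) -> list[int]:
        return list(range(self.n_zones, 0, -1))


def shortest_distance_to_polyline(point, polyline: BoundaryPolyline) -> float:
    """Minimum Euclidean distance from a point to any polyline segment."""
    p = np.asarray(point, dtype=float)
    a = polyline.vertices[:-1]
    b = polyline.vertices[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    if np.all(seg_len2 == 0):
        raise ValueError("degenerate zero-length polyline")
    # projection parameter of p on each segment, clamped to the segment
    t = np.einsum("ij,ij->i", p[None, :] - a, ab)
    t = np.divide(t, seg_len2, out=np.zeros_like(t), where=seg_len2 > 0)
    t = np.clip(t, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.hypot(*(p[None, :] - foot).T)
    return float(d.min())


def relative_distance(
    point, ventricular: BoundaryPolyline, pial: BoundaryPolyline
) -> float:
    """Normalized radial depth d1 / (d1 + d2) in [0, 1].

    0 means on the ventricular surface, 1 on the pia.
    """
    if ventricular.role != "ventricular" or pial.role != "pial":
        raise ValueError("boundary roles must be ventricular and pial")
    d1 = shortest_distance_to_polyline(point, ventricular)
    d2 = shortest_distance_to_polyline(point, pial)
    if d1 + d2 == 0:
        raise ValueError("point is on both boundaries; relative distance undefined")
    return d1 / (d1 + d2)


def bin_into_zones(rel_distances, n_zones: int = 10) -> ZoneDistribution:
    """Bin relative distances into ``n_zones`` equal-width zones.

    Bins are half-open [k/n, (k+1)/n) with the last bin closed at 1.0.
    """
    r = np.asarray(rel_distances, dtype=float)
    if r.size and (np.nanmin(r) < 0 or np.nanmax(r) > 1):
        raise ValueError("relative distances must lie in [0, 1]")
    idx = np.minimum((r * n_zones).astype(int), n_zones - 1)
    counts = np.bincount(idx, minlength=n_zones)
    return ZoneDistribution(counts=counts, n_zones=n_zones)


def arcsin_sqrt(p) -> np.ndarray | float:
    """Variance-stabilizing arcsin(sqrt(p)) transform of a proportion."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p_arr))
    return float(out) if np.isscalar(p) else out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_distributions(fraction_table: pd.DataFrame) -> dict:
    """Compare per-zone fraction distributions between genotypes.

    ``fraction_table`` is long-format with columns ``genotype``, ``replicate``,
    ``zone`` and ``fraction`` (fractions of each replicate summing to 1 over
    zones).  Fractions are arcsin(sqrt(p))-transformed, a two-way ANOVA with
    factors zone and genotype is fitted, and Tukey-adjusted pairwise genotype
    contrasts are computed within each zone.

    Returns a dict with keys ``anova`` (DataFrame of F statistics) and
    ``tukey`` (DataFrame with one row per zone x genotype pair, columns
    including ``p_adj`` and ``stars``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    required = {"genotype", "replicate", "zone", "fraction"}
    missing = required - set(fraction_table.columns)
    if missing:
        raise ValueError(f"fraction table missing columns: {sorted(missing)}")
    df = fraction_table.copy()
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes to compare")
    zones = sorted(df["zone"].unique())
    # balance check: every genotype x zone cell needs >= 2 replicates
    cell_counts = df.groupby(["genotype", "zone"]).size()
    if (cell_counts < 2).any():
        raise ValueError("unbalanced design: every genotype x zone needs >= 2 replicates")

    df["y"] = arcsin_sqrt(df["fraction"].to_numpy())
    model = ols("y ~ C(zone) * C(genotype)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    for z in zones:
        sub = df[df["zone"] == z]
        res = pairwise_tukeyhsd(sub["y"].to_numpy(), sub["genotype"].to_numpy())
        table = res.summary().data[1:]
        for g1, g2, meandiff, p_adj, lo, hi, reject in table:
            rows.append(
                {
                    "zone": z,
                    "group1": g1,
                    "group2": g2,
                    "mean_diff": float(meandiff),
                    "p_adj": float(p_adj),
                    "stars": _stars(float(p_adj)),
                    "significant": bool(reject),
                }
            )
    return {"anova": anova, "tukey": pd.DataFrame(rows)}
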