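"""Reporter-intensity tables -> per-protein dose-response competition profiles.

Channel normalization to equal total intensity, two-sample contrasts on
log2 intensities (log2 fold change + two-tailed t-test), the affinity-vs-capped
enrichment filter, and assembly of the per-dose log2FC feature matrix that
feeds clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ChannelDesign

__all__ = [
    "ReporterIntensityTable",
    "normalize_total_intensity",
    "compute_contrast",
    "enrichment_filter",
    "build_profile_matrix",
    "competition_profiles",
]


@dataclass
class ReporterIntensityTable:
    """Protein x channel reporter intensities plus the channel design.

    Zero or negative intensities are flagged as missing (NaN) on
    construction; downstream statistics exclude them pairwise.
    """

    intensities: pd.DataFrame  # index protein_id, columns channel_id
    design: list[ChannelDesign]

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.design]
        if list(self.intensities.columns) != ids:
            raise ValueError("intensity columns do not match channel design")
        vals = self.intensities.to_numpy(dtype=float)
        if (vals <= 0).any():
            vals = np.where(vals > 0, vals, np.nan)
            self.intensities = pd.DataFrame(
                vals, index=self.intensities.index, columns=self.intensities.columns
            )

    def channels(self, bead_type: str | None = None, dose: float | None = None) -> list[str]:
        out = []
        for c in self.design:
            if bead_type is not None and c.bead_type != bead_type:
                continue
            if dose is not None and c.dose != dose:
                continue
            out.append(c.channel_id)
        return out

    @property
    def doses(self) -> list[float]:
        """Nonzero affinity doses in ascending order."""
        return sorted({c.dose for c in self.design if c.bead_type == "affinity" and c.dose > 0})


def normalize_total_intensity(table: ReporterIntensityTable) -> ReporterIntensityTable:
    """Scale each channel so all channel totals equal the mean pre-normalization
    total.  Within-channel ratios, and the grand total, are preserved."""
    totals = table.intensities.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"channel(s) with zero total intensity: {list(zero.index)}")
    target = totals.mean()
    scaled = table.intensities * (target / totals)
    return ReporterIntensityTable(scaled, table.design)


def compute_contrast(
    table: ReporterIntensityTable,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein (log2FC, p_value) for group_a vs group_b.

    Statistics are computed on log2-transformed intensities: log2FC is the
    difference of group means and p comes from a two-tailed two-sample
    t-test (Student's by default; Welch via ``equal_var=False``).  At three
    replicates per group Student's test holds its nominal size, whereas
    Welch's is conservative.  Proteins with fewer than two finite
    replicates in either group are returned as missing.
    """
    if not group_a or not group_b:
        raise ValueError("both channel groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("channel groups overlap")
    la = np.log2(table.intensities[group_a].to_numpy(dtype=float))
    lb = np.log2(table.intensities[group_b].to_numpy(dtype=float))
    na = np.sum(np.isfinite(la), axis=1)
    nb = np.sum(np.isfinite(lb), axis=1)
    log2fc = np.nanmean(la, axis=1) - np.nanmean(lb, axis=1)
    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var, nan_policy="omit")
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance: equal means are maximally unsurprising,
    # unequal means with no spread are maximally surprising
    degenerate = ~np.isfinite(pvals) & (na >= 2) & (nb >= 2)
    pvals[degenerate & (np.abs(log2fc) < 1e-12)] = 1.0
    pvals[degenerate & (np.abs(log2fc) >= 1e-12)] = 0.0
    bad = (na < 2) | (nb < 2)
    log2fc[bad] = np.nan
    pvals[bad] = np.nan
    return pd.DataFrame({"log2fc": log2fc, "p_value": pvals}, index=table.intensities.index)


def enrichment_filter(
    profiles: pd.DataFrame, fc_cut: float = 0.6, p_cut: float = 0.05
) -> list[str]:
    """Proteins specifically captured by the affinity resin: enrichment
    log2FC > fc_cut AND p < p_cut (both strict).  Order-stable by protein id."""
    keep = (profiles["log2fc"] > fc_cut) & (profiles["p_value"] < p_cut)
    return sorted(profiles.index[keep.fillna(False)])


def build_profile_matrix(
    table: ReporterIntensityTable,
    doses: list[float] | None = None,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dose treated-vs-vehicle contrasts on affinity channels.

    Returns the protein x dose log2FC feature matrix and the companion
    p-value matrix, columns in ascending dose order.  Missing contrasts
    propagate as NaN.
    """
    if doses is None:
        doses = table.doses
    vehicle = table.channels("affinity", 0.0)
    available = set(table.doses)
    fc, pv = {}, {}
    for d in doses:
        if d not in available:
            raise ValueError(f"dose {d} µM absent from the channel design")
        treated = table.channels("affinity", d)
        contrast = compute_contrast(table, treated, vehicle, equal_var=equal_var)
        fc[d] = contrast["log2fc"]
        pv[d] = contrast["p_value"]
    order = sorted(doses)
    return (
        pd.DataFrame(fc)[order],
        pd.DataFrame(pv)[order],
    )


def competition_profiles(
    table: ReporterIntensityTable,
    fc_cut: float = 0.6,
    p_cut: float = 0.05,
    normalize: bool = True,
    equal_var: bool = True,
) -> dict:
    """Full proteomic stage: normalize, per-dose contrasts, enrichment.

    Returns a dict with the normalized table, the (log2FC, p) matrices,
    the enrichment contrast (vehicle affinity vs capped) and the enriched
    protein list.
    """
    if normalize:
        table = normalize_total_intensity(table)
    fc_matrix, p_matrix = build_profile_matrix(table, equal_var=equal_var)
    enrichment = compute_contrast(
        table, table.channels("affinity", 0.0), table.channels("capped"), equal_var=equal_var
    )
    enriched = enrichment_filter(enrichment, fc_cut=fc_cut, p_cut=p_cut)
    return {
        "table": table,
        "log2fc": fc_matrix,
        "p_values": p_matrix,
        "enrichment": enrichment,
        "enriched": enriched,
    }
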