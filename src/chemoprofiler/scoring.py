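"""AlphaFold-derived interface metrics and threshold-gated composite scoring.

LIA/LIS from the inter-chain PAE blocks, pDockQ/mpDockQ from interface
plDDT and contact counts, per-pair aggregation over the five predicted
models, the weighted constant k from the three minimum-acceptable
thresholds, and the min-max-normalized composite score used to rank
candidate interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance_matrix

__all__ = [
    "ThresholdConfig",
    "PDOCKQ_CONSTANTS",
    "MPDOCKQ_CONSTANTS",
    "compute_lia_lis",
    "compute_pdockq",
    "aggregate_models",
    "assign_weight_k",
    "composite_score",
]

#: Published sigmoid fit pDockQ = L / (1 + exp(-k (x - x0))) + b for dimers,
#: with x = mean interface plDDT * log10(interface contact count).
PDOCKQ_CONSTANTS = {"L": 0.724, "x0": 152.611, "k": 0.052, "b": 0.018}
#: Published fit for larger multimers (mpDockQ).
MPDOCKQ_CONSTANTS = {"L": 0.728, "x0": 309.375, "k": 0.098, "b": 0.262}


@dataclass(frozen=True)
class ThresholdConfig:
    """Minimum acceptable metric thresholds and the pass-count -> k map."""

    lia_min: float = 1610.0
    lis_min: float = 0.073
    dockq_min: float = 0.175
    k_map: dict[int, float] = field(
        default_factory=lambda: {3: 1.0, 2: 0.75, 1: 0.5, 0: 0.0}
    )
    pae_cutoff_lis: float = 12.0  # Å
    model_aggregation: str = "max"  # max | mean | best_by_dockq

    def __post_init__(self) -> None:
        if min(self.lia_min, self.lis_min, self.dockq_min) <= 0:
            raise ValueError("thresholds must be positive")
        if set(self.k_map) != {0, 1, 2, 3}:
            raise ValueError("k_map must have keys exactly {0,1,2,3}")
        ws = [self.k_map[i] for i in range(4)]
        if any(not 0 <= w <= 1 for w in ws) or any(a > b for a, b in zip(ws, ws[1:])):
            raise ValueError("k weights must lie in [0,1] and be non-decreasing in passes")
        if self.model_aggregation not in ("max", "mean", "best_by_dockq"):
            raise ValueError(f"unknown aggregation {self.model_aggregation!r}")


def compute_lia_lis(
    pae: np.ndarray, chain_split: int, cutoff: float = 12.0
) -> tuple[int, float]:
    """Local Interaction Area and Score from a PAE matrix.

    Over the union of the two inter-chain blocks (A->B and B->A), cells
    with PAE strictly below ``cutoff`` are interface cells.  LIA is their
    count; LIS is the mean of (cutoff - PAE)/cutoff over them (0 if none).
    """
    pae = np.asarray(pae, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("PAE matrix must be square")
    n = pae.shape[0]
    if not 0 < chain_split < n:
        raise ValueError("chain_split outside matrix")
    blocks = np.concatenate(
        [pae[:chain_split, chain_split:].ravel(), pae[chain_split:, :chain_split].ravel()]
    )
    interface = blocks[blocks < cutoff]
    lia = int(interface.size)
    lis = float(((cutoff - interface) / cutoff).mean()) if lia else 0.0
    return lia, lis


def compute_pdockq(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    plddt_a: np.ndarray,
    plddt_b: np.ndarray,
    contact_cutoff: float = 8.0,
    constants: dict[str, float] | None = None,
) -> float:
    """Docking-quality estimate from interface plDDT and contact count.

    Interface residues are inter-chain pairs whose representative-atom
    distance is <= ``contact_cutoff`` (coordinates are CB, falling back to
    CA for glycine, as supplied by the structure reader).  With
    x = mean interface plDDT * log10(contacts), the score is the published
    sigmoid L/(1+exp(-k(x-x0))) + b; zero contacts return the floor b.
    """
    c = constants or PDOCKQ_CONSTANTS
    plddt_a = np.asarray(plddt_a, dtype=float)
    plddt_b = np.asarray(plddt_b, dtype=float)
    if np.isnan(plddt_a).any() or np.isnan(plddt_b).any():
        raise ValueError("per-residue plDDT is required")
    d = distance_matrix(np.asarray(coords_a, float), np.asarray(coords_b, float))
    ia, ib = np.nonzero(d <= contact_cutoff)
    n_contacts = ia.size
    if n_contacts == 0:
        return float(c["b"])
    iface_plddt = np.concatenate([plddt_a[np.unique(ia)], plddt_b[np.unique(ib)]]).mean()
    x = iface_plddt * np.log10(n_contacts)
    return float(c["L"] / (1.0 + np.exp(-c["k"] * (x - c["x0"]))) + c["b"])


def aggregate_models(
    models: pd.DataFrame, config: ThresholdConfig = ThresholdConfig()
) -> pd.DataFrame:
    """Collapse the per-model metric table to one row per pair.

    Default rule is the per-metric maximum across models (best-model
    convention); ``mean`` averages each metric; ``best_by_dockq`` keeps the
    whole row of the model with the highest dockq.  Output carries the
    model count.
    """
    required = {"pair_id", "iptm", "lia", "lis", "dockq"}
    if not required <= set(models.columns):
        raise ValueError(f"metric table missing columns {sorted(required - set(models.columns))}")
    if models.empty:
        raise ValueError("no models to aggregate")
    metrics = ["iptm", "lia", "lis", "dockq"]
    g = models.groupby("pair_id", sort=True)
    if config.model_aggregation == "max":
        agg = g[metrics].max()
    elif config.model_aggregation == "mean":
        agg = g[metrics].mean()
    else:  # best_by_dockq
        idx = g["dockq"].idxmax()
        agg = models.loc[idx, ["pair_id"] + metrics].set_index("pair_id")
    agg["n_models"] = g.size()
    return agg.reset_index()


def assign_weight_k(
    aggregate: pd.Series | dict, thresholds: ThresholdConfig = ThresholdConfig()
) -> tuple[int, float]:
    """Pass count against the three minimum-acceptable thresholds (>=, since
    they are minima) and the resulting weighted constant k."""
    passes = sum(
        [
            bool(aggregate["lia"] >= thresholds.lia_min),
            bool(aggregate["lis"] >= thresholds.lis_min),
            bool(aggregate["dockq"] >= thresholds.dockq_min),
        ]
    )
    return passes, thresholds.k_map[passes]


def composite_score(
    cohort: pd.DataFrame, thresholds: ThresholdConfig = ThresholdConfig()
) -> pd.DataFrame:
    """Threshold-gated composite score and ranking over a cohort of pairs.

    Each of lia/lis/dockq is min-max normalized over the cohort (0 when the
    cohort has no spread in that metric); composite = k * (n_lia + n_lis +
    n_dockq), so a pair passing no threshold scores 0 regardless of
    magnitude.  Pairs are ranked by descending composite, ties broken by
    descending ipTM then pair id.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    out = cohort.copy().reset_index(drop=True)
    pk = out.apply(lambda r: assign_weight_k(r, thresholds), axis=1)
    out["passes"] = [p for p, _ in pk]
    out["k"] = [k for _, k in pk]
    for m in ("lia", "lis", "dockq"):
        lo, hi = out[m].min(), out[m].max()
        out[f"n_{m}"] = 0.0 if hi == lo else (out[m] - lo) / (hi - lo)
    out["composite"] = out["k"] * (out["n_lia"] + out["n_lis"] + out["n_dockq"])
    out = out.sort_values(
        ["composite", "iptm", "pair_id"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
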