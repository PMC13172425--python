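"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: reporter-intensity
tables emulating a TMT competition experiment (dose-dependent occupancy
curves for planted complex members against a flat background), per-model
AlphaFold metric tables in which planted interactors clear the composite-score
thresholds, and toy two-chain complexes with controlled CA-CA distances,
PAE and contact probabilities.  Each generator is a pure function of its
arguments plus a seed, so regeneration is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelDesign",
    "PlantedProteinSpec",
    "PlantedInterfaceSpec",
    "default_design",
    "default_protein_panel",
    "generate_competition_dataset",
    "generate_af_metric_table",
    "generate_toy_complex",
    "ToyComplex",
    "write_competition_dataset",
    "write_toy_complex",
]

#: Default competitor dose grid (µM) for the proteomic competition design.
DEFAULT_DOSES = (0.0, 0.1, 1.0, 10.0)
#: Wider grid mirroring the blot-style titration.
WIDE_DOSES = (0.0, 0.01, 0.1, 1.0, 10.0, 30.0)
DEFAULT_REPLICATES = 3

# Metric ranges used by the AF-table generator.  True interactors draw every
# metric from the "hit" band, whose lower edge sits strictly above the
# composite-score thresholds (LIA 1610, LIS 0.073, dockQ 0.175); decoys draw
# failing metrics below threshold and any passing metric from a band that
# stays below the hit band, so planted pairs always aggregate on top.
_LIA_THRESH, _LIS_THRESH, _DOCKQ_THRESH = 1610.0, 0.073, 0.175
_HIT_BANDS = {"lia": (2000.0, 4000.0), "lis": (0.15, 0.50), "dockq": (0.30, 0.70)}
_DECOY_PASS_BANDS = {"lia": (1650.0, 1900.0), "lis": (0.08, 0.12), "dockq": (0.18, 0.25)}
_DECOY_FAIL_BANDS = {"lia": (0.0, 1200.0), "lis": (0.0, 0.06), "dockq": (0.0, 0.14)}


@dataclass(frozen=True)
class ChannelDesign:
    """One labeled channel: competitor dose, replicate and bead type."""

    channel_id: str
    dose: float  # µM; 0 = vehicle
    replicate: int
    bead_type: str  # "affinity" or "capped"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"negative dose for channel {self.channel_id}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1 ({self.channel_id})")
        if self.bead_type not in ("affinity", "capped"):
            raise ValueError(f"unknown bead_type {self.bead_type!r}")


@dataclass(frozen=True)
class PlantedProteinSpec:
    """Ground-truth behaviour of one protein in the competition experiment.

    ``complex_member`` proteins follow a four-parameter logistic occupancy
    curve in competitor dose; ``other_coa_binder`` and ``background``
    proteins are dose-flat.  ``capped_fraction`` sets the fraction of the
    baseline captured on the ethanolamine-capped control beads.
    """

    protein_id: str
    baseline_intensity: float
    role: str = "background"  # complex_member | other_coa_binder | background
    ic50: float = math.inf  # µM
    hill: float = 1.0
    nonspecific_fraction: float = 0.0
    capped_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_intensity <= 0:
            raise ValueError(f"baseline must be positive ({self.protein_id})")
        if self.role not in ("complex_member", "other_coa_binder", "background"):
            raise ValueError(f"unknown role {self.role!r} ({self.protein_id})")
        if self.role == "complex_member" and not math.isfinite(self.ic50):
            raise ValueError(f"complex member {self.protein_id} needs a finite ic50")
        if not 0 <= self.nonspecific_fraction <= 1:
            raise ValueError("nonspecific_fraction outside [0,1]")
        if not 0 <= self.capped_fraction <= 1:
            raise ValueError("capped_fraction outside [0,1]")

    def occupancy(self, dose: float) -> float:
        """Captured fraction f(dose) on affinity beads."""
        if self.role != "complex_member" or dose == 0:
            return 1.0
        ns = self.nonspecific_fraction
        return ns + (1.0 - ns) / (1.0 + (dose / self.ic50) ** self.hill)


def default_design(
    doses: tuple[float, ...] = DEFAULT_DOSES,
    n_replicates: int = DEFAULT_REPLICATES,
    n_capped: int = DEFAULT_REPLICATES,
) -> list[ChannelDesign]:
    """The standard competition plex: every dose x replicate on affinity
    beads plus vehicle capped-bead control channels."""
    design = [
        ChannelDesign(f"D{d:g}_R{r}", d, r, "affinity")
        for d in doses
        for r in range(1, n_replicates + 1)
    ]
    design += [ChannelDesign(f"CAP_R{r}", 0.0, r, "capped") for r in range(1, n_capped + 1)]
    _validate_design(design)
    return design


def _validate_design(design: list[ChannelDesign]) -> None:
    keys = [(c.dose, c.replicate, c.bead_type) for c in design]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (dose, replicate, bead_type) in design")
    if not any(c.dose == 0 and c.bead_type == "affinity" for c in design):
        raise ValueError("design lacks a vehicle affinity channel")
    if not any(c.bead_type == "capped" for c in design):
        raise ValueError("design lacks a capped control channel")


def default_protein_panel(
    n_members: int = 10,
    n_background: int = 290,
    member_ic50s: tuple[float, ...] = (0.05, 0.5),
    seed: int = 0,
) -> list[PlantedProteinSpec]:
    """Planted panel used throughout: dose-sensitive complex members on a
    background of dose-flat non-specific binders.

    Members alternate between the given IC50s, capture specifically
    (capped_fraction 0.05); background proteins bind both bead types alike.
    Baselines are log-uniform over two orders of magnitude.
    """
    rng = np.random.default_rng(seed)
    panel: list[PlantedProteinSpec] = []
    for i in range(n_members):
        panel.append(
            PlantedProteinSpec(
                protein_id=f"MEMBER{i + 1:03d}",
                baseline_intensity=float(10 ** rng.uniform(5, 7)),
                role="complex_member",
                ic50=member_ic50s[i % len(member_ic50s)],
                hill=1.0,
                nonspecific_fraction=0.05,
                capped_fraction=0.05,
            )
        )
    for i in range(n_background):
        panel.append(
            PlantedProteinSpec(
                protein_id=f"BG{i + 1:04d}",
                baseline_intensity=float(10 ** rng.uniform(5, 7)),
                role="background",
                capped_fraction=1.0,
            )
        )
    return panel


def generate_competition_dataset(
    design: list[ChannelDesign],
    proteins: list[PlantedProteinSpec],
    noise_cv: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Reporter-intensity table (protein x channel) for a planted panel.

    intensity = baseline * f(dose) * eps on affinity channels and
    baseline * capped_fraction * eps on capped channels, with eps lognormal
    of unit mean and coefficient of variation ``noise_cv``.

    Returns a DataFrame indexed by protein_id with one column per
    channel_id; the design travels alongside (see
    :func:`write_competition_dataset`).
    """
    if not design or not proteins:
        raise ValueError("design and protein list must be non-empty")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    _validate_design(design)
    rng = np.random.default_rng(seed)
    # lognormal with E[eps]=1 and CV=noise_cv
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    mu = -0.5 * sigma**2
    expected = np.empty((len(proteins), len(design)))
    for i, p in enumerate(proteins):
        for j, ch in enumerate(design):
            if ch.bead_type == "capped":
                expected[i, j] = p.baseline_intensity * p.capped_fraction
            else:
                expected[i, j] = p.baseline_intensity * p.occupancy(ch.dose)
    eps = np.exp(rng.normal(mu, sigma, size=expected.shape)) if noise_cv > 0 else 1.0
    intensities = expected * eps
    # capped_fraction 0 would yield zero intensity; keep strictly positive
    intensities = np.maximum(intensities, 1e-12)
    return pd.DataFrame(
        intensities,
        index=pd.Index([p.protein_id for p in proteins], name="protein_id"),
        columns=[c.channel_id for c in design],
    )


def design_frame(design: list[ChannelDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel_id": [c.channel_id for c in design],
            "dose_uM": [c.dose for c in design],
            "replicate": [c.replicate for c in design],
            "bead_type": [c.bead_type for c in design],
        }
    )


def generate_af_metric_table(
    n_pairs: int,
    true_interactors: set[str] | frozenset[str],
    n_models: int = 5,
    seed: int = 0,
    bait: str = "BAIT",
) -> pd.DataFrame:
    """Per-model AlphaFold metric table with planted true interactors.

    Each pair gets ``n_models`` rows of (iptm, lia, lis, dockq).  For true
    interactors the best model clears all three composite-score thresholds;
    decoy pairs fail at least one metric in every model, so any per-model
    aggregation leaves them below threshold on that metric.
    """
    true_interactors = set(true_interactors)
    if n_pairs < len(true_interactors):
        raise ValueError("n_pairs smaller than the number of true interactors")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = sorted(true_interactors) + [
        f"PREY{i + 1:03d}" for i in range(n_pairs - len(true_interactors))
    ]
    rows = []
    for cand in candidates:
        pair = f"{bait}__{cand}"
        is_true = cand in true_interactors
        if is_true:
            fail = frozenset()
        else:
            # decoys fail 1-3 metrics, drawn once per pair
            n_fail = int(rng.integers(1, 4))
            fail = frozenset(rng.choice(["lia", "lis", "dockq"], size=n_fail, replace=False))
        for model in range(1, n_models + 1):
            rec = {"pair_id": pair, "model_id": model}
            for metric in ("lia", "lis", "dockq"):
                if is_true:
                    lo, hi = _HIT_BANDS[metric]
                elif metric in fail:
                    lo, hi = _DECOY_FAIL_BANDS[metric]
                else:
                    lo, hi = _DECOY_PASS_BANDS[metric]
                rec[metric] = float(rng.uniform(lo, hi))
            rec["lia"] = float(round(rec["lia"]))
            rec["iptm"] = float(rng.uniform(0.6, 0.95) if is_true else rng.uniform(0.1, 0.45))
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["pair_id", "model_id", "iptm", "lia", "lis", "dockq"])
    return df


@dataclass(frozen=True)
class PlantedInterfaceSpec:
    """Geometry and confidence layout of a planted two-chain interface."""

    chain_lengths: tuple[int, int]
    true_contact_pairs: frozenset[tuple[int, int]]  # 1-based (resA, resB)
    interface_distance: float = 5.0  # Å, CA-CA for true pairs
    background_distance: float = 20.0  # Å, lower bound for all other pairs
    pae_interface: float = 5.0
    pae_background: float = 28.0
    prob_interface: float = 0.9
    prob_background: float = 0.0
    plddt_interface: float = 90.0
    plddt_background: float = 60.0

    def __post_init__(self) -> None:
        na, nb = self.chain_lengths
        if na < 1 or nb < 1:
            raise ValueError("chain lengths must be >= 1")
        if not self.interface_distance < self.background_distance:
            raise ValueError("interface_distance must be < background_distance")
        for i, j in self.true_contact_pairs:
            if not (1 <= i <= na and 1 <= j <= nb):
                raise ValueError(f"true pair ({i},{j}) outside chain bounds")


@dataclass(frozen=True)
class ToyComplex:
    """Emitted toy complex: coordinates plus confidence matrices.

    ``pae`` and ``contact_probs`` are square over the concatenated
    chain-A-then-chain-B residue order, matching the AlphaFold layout.
    """

    chain_lengths: tuple[int, int]
    coords_a: np.ndarray  # (nA, 3) CA coordinates, Å
    coords_b: np.ndarray
    plddt_a: np.ndarray
    plddt_b: np.ndarray
    pae: np.ndarray
    contact_probs: np.ndarray


def generate_toy_complex(spec: PlantedInterfaceSpec, seed: int = 0) -> ToyComplex:
    """Place two straight-line chains so each planted contact pair sits at
    exactly ``interface_distance`` and every other inter-chain CA pair is at
    least ``background_distance`` apart.

    Residues of both chains are spaced ``background + interface + 1`` Å apart
    along x; chain B starts far from chain A and planted chain-B residues
    are pulled to a point directly above their chain-A partner.  A chain-B
    residue planted against two distinct chain-A residues cannot satisfy
    both distances and raises a generation error.
    """
    na, nb = spec.chain_lengths
    spacing = spec.background_distance + spec.interface_distance + 1.0
    far = spec.background_distance + spacing

    partners: dict[int, set[int]] = {}
    for i, j in spec.true_contact_pairs:
        partners.setdefault(j, set()).add(i)
    for j, ais in partners.items():
        if len(ais) > 1:
            raise RuntimeError(
                f"placement failure: chain-B residue {j} planted against "
                f"multiple chain-A residues {sorted(ais)}"
            )

    coords_a = np.zeros((na, 3))
    coords_a[:, 0] = np.arange(na) * spacing
    coords_b = np.zeros((nb, 3))
    coords_b[:, 0] = np.arange(nb) * spacing + spacing / 2.0
    coords_b[:, 1] = far
    for j, ais in sorted(partners.items()):
        (i,) = ais
        coords_b[j - 1] = coords_a[i - 1] + np.array([0.0, spec.interface_distance, 0.0])

    n = na + nb
    pae = np.full((n, n), spec.pae_background)
    np.fill_diagonal(pae, 0.0)
    probs = np.full((n, n), spec.prob_background)
    plddt_a = np.full(na, spec.plddt_background)
    plddt_b = np.full(nb, spec.plddt_background)
    for i, j in spec.true_contact_pairs:
        ia, ib = i - 1, na + j - 1
        pae[ia, ib] = pae[ib, ia] = spec.pae_interface
        probs[ia, ib] = probs[ib, ia] = spec.prob_interface
        plddt_a[i - 1] = spec.plddt_interface
        plddt_b[j - 1] = spec.plddt_interface

    toy = ToyComplex((na, nb), coords_a, coords_b, plddt_a, plddt_b, pae, probs)
    _check_placement(toy, spec)
    return toy


def _check_placement(toy: ToyComplex, spec: PlantedInterfaceSpec, tol: float = 0.1) -> None:
    from scipy.spatial import distance_matrix

    d = distance_matrix(toy.coords_a, toy.coords_b)
    true = {(i - 1, j - 1) for i, j in spec.true_contact_pairs}
    for (i, j), dist in np.ndenumerate(d):
        if (i, j) in true:
            if abs(dist - spec.interface_distance) > tol:
                raise RuntimeError(f"placement failure: pair ({i + 1},{j + 1}) at {dist:.2f} Å")
        elif dist < spec.background_distance:
            raise RuntimeError(
                f"placement failure: non-contact pair ({i + 1},{j + 1}) at {dist:.2f} Å "
                f"< background {spec.background_distance} Å"
            )


# ---------------------------------------------------------------------------
# writers

def write_competition_dataset(
    out_dir: str | Path,
    intensities: pd.DataFrame,
    design: list[ChannelDesign],
    proteins: list[PlantedProteinSpec] | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intensities.to_csv(out / "intensities.tsv", sep="\t")
    design_frame(design).to_csv(out / "design.tsv", sep="\t", index=False)
    if proteins is not None:
        manifest = {
            "complex_members": [p.protein_id for p in proteins if p.role == "complex_member"],
            "ic50_uM": {p.protein_id: p.ic50 for p in proteins if p.role == "complex_member"},
        }
        (out / "ground_truth.json").write_text(json.dumps(manifest, indent=1))


def write_toy_complex(out_dir: str | Path, toy: ToyComplex, name: str = "toy") -> None:
    """Write PDB (plDDT in the B-factor column), PAE JSON in the AlphaFold
    dialect and an AF3-style summary JSON with ``contact_probs``."""
    import gemmi

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_name, coords, plddt in (
        ("A", toy.coords_a, toy.plddt_a),
        ("B", toy.coords_b, toy.plddt_b),
    ):
        chain = gemmi.Chain(chain_name)
        for idx, (xyz, b) in enumerate(zip(coords, plddt), start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(idx, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.b_iso = float(b)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(out / f"{name}.pdb"))
    (out / f"{name}_pae.json").write_text(
        json.dumps({"predicted_aligned_error": toy.pae.tolist()})
    )
    (out / f"{name}_summary.json").write_text(
        json.dumps({"contact_probs": toy.contact_probs.tolist()})
    )
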