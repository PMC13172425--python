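"""Interface residue contacts from predicted two-chain structures.

AlphaFold2-style rules (CA-CA distance under 8 Å for contacts; under 6 Å
with symmetrized PAE under 25.7 for high-confidence contacts), the
AlphaFold3 rule (contact probability above 0.1), and the consensus of the
two.  Residue pairs are unordered (chain A residue, chain B residue),
reported 1-based; the PAE and contact-probability matrices are indexed in
concatenated chain-A-then-chain-B order, matching the AlphaFold layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import distance_matrix

__all__ = [
    "StructurePair",
    "load_structure_pair",
    "load_pae",
    "load_contact_probs",
    "ca_distance_matrix",
    "af2_contacts",
    "af2_high_confidence",
    "af3_contacts",
    "consensus_residues",
    "contact_table",
]


@dataclass
class StructurePair:
    """Two polymer chains with per-residue CA coordinates and plDDT.

    ``cb_a``/``cb_b`` hold the CB coordinate where one exists (CA for
    glycine and CA-only models), the convention used for docking-quality
    interface counting.
    """

    chain_ids: tuple[str, str]
    res_ids_a: list[int]  # author numbering, per chain
    res_ids_b: list[int]
    res_names_a: list[str]
    res_names_b: list[str]
    ca_a: np.ndarray  # (nA, 3)
    ca_b: np.ndarray
    cb_a: np.ndarray
    cb_b: np.ndarray
    plddt_a: np.ndarray
    plddt_b: np.ndarray

    @property
    def n_a(self) -> int:
        return len(self.res_ids_a)

    @property
    def n_b(self) -> int:
        return len(self.res_ids_b)


def load_structure_pair(path: str | Path) -> StructurePair:
    """Read a two-chain PDB/mmCIF model; plDDT is taken from the B-factor
    column.  Hetero-residues and waters are ignored; a polymer residue
    without a CA atom is an error naming the residue."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_ligands_and_waters()
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 2:
        raise ValueError(f"{path}: expected exactly 2 chains, found {len(chains)}")
    parsed = []
    for ch in chains:
        res_ids, names, cas, cbs, plddts = [], [], [], [], []
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None:
                raise ValueError(f"{path}: residue {ch.name}/{res.seqid.num} {res.name} has no CA")
            cb = res.find_atom("CB", "*")
            rep = cb if (cb is not None and res.name != "GLY") else ca
            res_ids.append(res.seqid.num)
            names.append(res.name)
            cas.append([ca.pos.x, ca.pos.y, ca.pos.z])
            cbs.append([rep.pos.x, rep.pos.y, rep.pos.z])
            plddts.append(ca.b_iso)
        parsed.append((ch.name, res_ids, names, np.array(cas), np.array(cbs), np.array(plddts)))
    (na, ra, rna, caa, cba, pa), (nb, rb, rnb, cab, cbb, pb) = parsed
    return StructurePair((na, nb), ra, rb, rna, rnb, caa, cab, cba, cbb, pa, pb)


def load_pae(path: str | Path) -> np.ndarray:
    """PAE JSON in either AlphaFold dialect:
    {"predicted_aligned_error": [[...]]} or [{"predicted_aligned_error": ...}]."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        data = data[0]
    try:
        pae = np.asarray(data["predicted_aligned_error"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: no 'predicted_aligned_error' key") from exc
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError(f"{path}: PAE matrix is not square")
    return pae


def load_contact_probs(path: str | Path) -> np.ndarray:
    """AlphaFold3 summary JSON: the 'contact_probs' matrix."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        data = data[0]
    try:
        probs = np.asarray(data["contact_probs"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: no 'contact_probs' key") from exc
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError(f"{path}: contact_probs matrix is not square")
    return probs


def ca_distance_matrix(pair: StructurePair) -> np.ndarray:
    """|chainA| x |chainB| Euclidean CA-CA distances in Å."""
    if pair.n_a == 0 or pair.n_b == 0:
        raise ValueError("both chains must be non-empty")
    return distance_matrix(pair.ca_a, pair.ca_b)


def af2_contacts(dist: np.ndarray, dist_cut: float = 8.0) -> set[tuple[int, int]]:
    """Inter-chain residue pairs (1-based positional indices) with CA-CA
    distance strictly under ``dist_cut``."""
    ia, ib = np.nonzero(dist < dist_cut)
    return {(int(i) + 1, int(j) + 1) for i, j in zip(ia, ib)}


def symmetrize_pae(pae: np.ndarray, mode: str = "mean") -> np.ndarray:
    if mode == "mean":
        return 0.5 * (pae + pae.T)
    if mode == "min":
        return np.minimum(pae, pae.T)
    if mode == "max":
        return np.maximum(pae, pae.T)
    raise ValueError(f"unknown symmetrization {mode!r}")


def af2_high_confidence(
    dist: np.ndarray,
    pae: np.ndarray,
    chain_split: int,
    dist_cut: float = 6.0,
    pae_cut: float = 25.7,
    pae_mode: str = "mean",
) -> set[tuple[int, int]]:
    """Highly interacting residue pairs: CA-CA distance strictly under
    ``dist_cut`` and symmetrized PAE (mean of the two directions by
    default) strictly under ``pae_cut``."""
    na, nb = dist.shape
    if pae.shape != (na + nb, na + nb):
        raise ValueError(
            f"PAE size {pae.shape} does not match {na}+{nb} concatenated residues"
        )
    sym = symmetrize_pae(pae, pae_mode)
    inter_pae = sym[:chain_split, chain_split:]
    ia, ib = np.nonzero((dist < dist_cut) & (inter_pae < pae_cut))
    return {(int(i) + 1, int(j) + 1) for i, j in zip(ia, ib)}


def af3_contacts(
    probs: np.ndarray, chain_split: int, prob_cut: float = 0.1
) -> set[tuple[int, int]]:
    """Inter-chain cells of the contact-probability matrix strictly above
    ``prob_cut``; symmetric cells count once per unordered pair."""
    probs = np.asarray(probs, dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("contact probabilities must lie in [0,1]")
    n = probs.shape[0]
    if not 0 < chain_split < n:
        raise ValueError("chain_split outside matrix")
    block = np.maximum(probs[:chain_split, chain_split:], probs[chain_split:, :chain_split].T)
    ia, ib = np.nonzero(block > prob_cut)
    return {(int(i) + 1, int(j) + 1) for i, j in zip(ia, ib)}


def consensus_residues(
    af2_high: set[tuple[int, int]], af3: set[tuple[int, int]]
) -> tuple[set[tuple[int, int]], set[tuple[str, int]]]:
    """Overlap of the AF2 high-confidence and AF3 contact sets: the pair
    intersection plus the residues appearing in at least one consensus
    pair, tagged by chain."""
    pairs = af2_high & af3
    residues = {("A", i) for i, _ in pairs} | {("B", j) for _, j in pairs}
    return pairs, residues


def contact_table(
    pair: StructurePair,
    pae: np.ndarray,
    probs: np.ndarray | None = None,
    dist_cut: float = 8.0,
    high_dist_cut: float = 6.0,
    pae_cut: float = 25.7,
    prob_cut: float = 0.1,
    pae_mode: str = "mean",
) -> pd.DataFrame:
    """One row per inter-chain residue pair within ``dist_cut``, with the
    distance, symmetrized PAE, contact probability and all flags."""
    dist = ca_distance_matrix(pair)
    split = pair.n_a
    contacts = af2_contacts(dist, dist_cut)
    high = af2_high_confidence(dist, pae, split, high_dist_cut, pae_cut, pae_mode)
    af3 = af3_contacts(probs, split, prob_cut) if probs is not None else set()
    consensus, _ = consensus_residues(high, af3)
    sym = symmetrize_pae(pae, pae_mode)
    rows = []
    for i, j in sorted(contacts | high | af3):
        rows.append(
            {
                "res_a": pair.res_ids_a[i - 1],
                "res_b": pair.res_ids_b[j - 1],
                "ca_distance": float(dist[i - 1, j - 1]),
                "pae": float(sym[i - 1, split + j - 1]),
                "contact_prob": float(probs[i - 1, split + j - 1]) if probs is not None else np.nan,
                "is_contact": (i, j) in contacts,
                "is_high_confidence": (i, j) in high,
                "in_af3": (i, j) in af3,
                "in_consensus": (i, j) in consensus,
            }
        )
    cols = [
        "res_a", "res_b", "ca_distance", "pae", "contact_prob",
        "is_contact", "is_high_confidence", "in_af3", "in_consensus",
    ]
    return pd.DataFrame(rows, columns=cols)
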