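"""Similarity search and read-across support.

A query compound is compared to every reference compound by Tanimoto
similarity on the raw 1191-bit [MACCS ‖ Morgan] fingerprint; the top hits
are returned together with the maximum common substructure (MCS) shared
with the query, and their experimental endpoint activities are extracted
from the activity matrix so an assessor can transfer evidence from close
analogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chemprep import ActivityMatrix
from .features import fingerprint

logger = logging.getLogger(__name__)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b| for binary fingerprints; degenerate all-zero pair
    is defined as 1.0 (identical emptiness) and logged."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        logger.debug("tanimoto of two all-zero fingerprints: defined as 1.0")
        return 1.0
    return int(np.sum(a & b)) / union


@dataclass
class SimilarityHit:
    compound_id: str
    tanimoto: float
    rank: int
    mcs_smarts: str | None = None
    mcs_atom_count: int | None = None
    mcs_approximate: bool = False


def rank_similar(
    query_structure: str,
    reference_corpus: dict[str, str] | list[tuple[str, str]],
    top_n: int = 4,
    reference_fingerprints: dict[str, np.ndarray] | None = None,
    compute_mcs: bool = False,
    mcs_timeout_s: int = 10,
) -> list[SimilarityHit]:
    """Reference compounds ranked by Tanimoto similarity to the query.

    Ties break by compound_id ascending; ranks are consecutive from 1.  A
    query present in the corpus ranks first at similarity 1.0.  Pass
    precomputed ``reference_fingerprints`` to amortise repeated queries.
    """
    corpus = dict(reference_corpus)
    if not corpus:
        raise ValueError("empty reference corpus")
    qfp = fingerprint(query_structure)
    sims = []
    for cid, smiles in corpus.items():
        rfp = (
            reference_fingerprints[cid]
            if reference_fingerprints is not None
            else fingerprint(smiles)
        )
        sims.append((cid, tanimoto(qfp, rfp)))
    sims.sort(key=lambda t: (-t[1], t[0]))
    hits = [
        SimilarityHit(cid, float(sim), rank)
        for rank, (cid, sim) in enumerate(sims[:top_n], start=1)
    ]
    if compute_mcs:
        for h in hits:
            h.mcs_smarts, h.mcs_atom_count, h.mcs_approximate = mcs_pair(
                query_structure, corpus[h.compound_id], timeout_s=mcs_timeout_s
            )
    return hits


def mcs_pair(
    query_structure: str, hit_structure: str, timeout_s: int = 10
) -> tuple[str | None, int | None, bool]:
    """Connected maximum common substructure of two molecules with
    ring-bond matching (aromatic and aliphatic rings never merge).

    Returns ``(smarts, atom_count, approximate)``; a timeout yields the
    best-so-far result flagged approximate, never an error.
    """
    mols = [Chem.MolFromSmiles(query_structure), Chem.MolFromSmiles(hit_structure)]
    if any(m is None for m in mols):
        raise ValueError("unparseable structure in MCS pair")
    res = rdFMCS.FindMCS(
        mols,
        ringMatchesRingOnly=True,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        completeRingsOnly=False,
        timeout=timeout_s,
    )
    if res.numAtoms == 0:
        return None, 0, bool(res.canceled)
    return res.smartsString, int(res.numAtoms), bool(res.canceled)


def extract_activities(
    hit_ids: list[str], activity_matrix: ActivityMatrix
) -> dict[str, dict]:
    """Per hit: the endpoint → hitcall map over tested endpoints only
    (missing is not 0), plus tested/active counts."""
    known = set(activity_matrix.compounds) | set(activity_matrix.structures)
    unknown = [h for h in hit_ids if h not in known]
    if unknown:
        raise KeyError(f"compound ids absent from activity matrix: {unknown}")
    table = {}
    for cid in hit_ids:
        labels = activity_matrix.labels_for(cid)
        table[cid] = {
            "activities": labels,
            "n_tested": len(labels),
            "n_active": sum(1 for v in labels.values() if v == 1),
        }
    return table
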