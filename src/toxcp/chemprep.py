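"""Structure standardisation and activity-matrix preparation.

Raw compound libraries arrive as SMILES with per-endpoint binary hitcalls.
Before any modelling, every structure is pushed through a deterministic
standardisation chain (organic filter, counter-ion stripping, neutralisation,
tautomer canonicalisation, size filter) and duplicate measurements are
resolved: agreeing replicates collapse to one record, conflicting replicates
are discarded entirely.  The surviving records form a sparse compound ×
endpoint activity matrix of {0, 1} hitcalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Elements permitted in a kept (organic) structure.
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

#: Counter-ions and solvents stripped from multi-component inputs.  The list
#: is deliberately small and editable; it covers the salts that dominate
#: screening libraries.
SALT_SOLVENT_SMARTS: tuple[str, ...] = (
    "[Li+]", "[Na+]", "[K+]", "[Rb+]", "[Cs+]",
    "[Mg+2]", "[Ca+2]", "[Ba+2]", "[Zn+2]", "[Al+3]",
    "[F-]", "[Cl-]", "[Br-]", "[I-]",
    "F", "Cl", "Br", "I",                  # neutral hydrohalic acids
    "[NH4+]", "N",
    "[OH-]",
    "O",                                   # water
    "[O-]S([O-])(=O)=O",                   # sulfate
    "OS(O)(=O)=O",
    "[O-][N+]([O-])=O",                    # nitrate
    "O[N+]([O-])=O",
    "[O-]C(=O)C",                          # acetate
    "OC(=O)C",
    "[O-]C(=O)C(F)(F)F",                   # trifluoroacetate
    "OC(=O)C(F)(F)F",
    "OS(=O)(=O)C",                         # mesylate
    "[O-]S(=O)(=O)C",
    "OS(=O)(=O)c1ccc(C)cc1",               # tosylate
    "[O-]S(=O)(=O)c1ccc(C)cc1",
    "OC(=O)C(O)C(O)C(O)=O",                # tartrate
    "OC(=O)\\C=C/C(O)=O",                  # maleate
    "OC(=O)/C=C/C(O)=O",                   # fumarate
    "CS(C)=O",                             # DMSO
    "CC(C)O",                              # isopropanol
    "CCO",                                 # ethanol
    "CO",                                  # methanol
)


class RejectReason(str, Enum):
    UNPARSEABLE = "unparseable"
    NON_ORGANIC = "non_organic"
    MIXTURE = "mixture"
    TOO_SMALL = "too_small"
    SALT_ONLY = "salt_only"


@dataclass(frozen=True)
class StandardizationResult:
    """Outcome of standardising one raw structure.

    ``status`` is ``"kept"`` or ``"rejected"``; a kept result carries the
    canonical SMILES of the single surviving component (guaranteed organic,
    connected and with at least three heavy atoms), a rejected one carries
    the reason.
    """

    status: str
    reason: RejectReason | None = None
    standardized_structure: str | None = None

    @property
    def kept(self) -> bool:
        return self.status == "kept"


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    structure: str
    source_labels: dict[str, int] = field(default_factory=dict)


@dataclass
class ActivityMatrix:
    """Sparse compounds × endpoints matrix of binary hitcalls.

    Backed by a long-form DataFrame with columns ``compound_id``,
    ``endpoint`` and ``label``; absence of a row means the pair was never
    tested (missing is not 0).
    """

    compounds: list[str]
    endpoints: list[str]
    values: pd.DataFrame  # columns: compound_id, endpoint, label
    structures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.values.duplicated(subset=["compound_id", "endpoint"])
        if dup.any():
            raise ValueError("duplicate (compound, endpoint) entries in matrix")

    def __len__(self) -> int:
        return len(self.values)

    def labels_for(self, compound_id: str) -> dict[str, int]:
        sub = self.values[self.values["compound_id"] == compound_id]
        return dict(zip(sub["endpoint"], sub["label"].astype(int)))

    def endpoint_data(self, endpoint: str) -> pd.DataFrame:
        return self.values[self.values["endpoint"] == endpoint]

    def class_counts(self, endpoint: str) -> tuple[int, int]:
        """(n_active, n_inactive) for one endpoint."""
        sub = self.endpoint_data(endpoint)
        n_active = int((sub["label"] == 1).sum())
        return n_active, len(sub) - n_active

    def to_wide(self) -> pd.DataFrame:
        return self.values.pivot(index="compound_id", columns="endpoint", values="label")


_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()
_SALT_MOLS = tuple(
    Chem.CanonSmiles(s) for s in SALT_SOLVENT_SMARTS if Chem.MolFromSmiles(s)
)


def _is_salt_component(canonical_smiles: str) -> bool:
    return canonical_smiles in _SALT_MOLS


def standardize_molecule(structure: str, canonical_tautomer: bool = True) -> StandardizationResult:
    """Standardise one raw structure to its canonical organic form.

    Chain: parse → carbon check → split components and strip known
    counter-ions/solvents → reject residual mixtures → neutralise formal
    charges → allowed-element check → canonical tautomer → reject fragments
    with fewer than three heavy atoms → canonical SMILES.  Deterministic,
    idempotent, never raises on bad input.
    """
    if not isinstance(structure, str) or not structure.strip():
        return StandardizationResult("rejected", RejectReason.UNPARSEABLE)

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        return StandardizationResult("rejected", RejectReason.UNPARSEABLE)

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols:
        return StandardizationResult("rejected", RejectReason.NON_ORGANIC)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        survivors = list(frags)
    else:
        survivors = [f for f in frags if not _is_salt_component(Chem.MolToSmiles(f))]
        if not survivors:
            # every component is a known counter-ion/solvent: fall back to the
            # largest carbon-containing one rather than stripping to nothing
            organics = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
            if not organics:
                return StandardizationResult("rejected", RejectReason.SALT_ONLY)
            survivors = [max(organics, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))]
    if len(survivors) > 1:
        return StandardizationResult("rejected", RejectReason.MIXTURE)

    mol = survivors[0]
    try:
        mol = _UNCHARGER.uncharge(mol)
        if canonical_tautomer:
            mol = _TAUTOMERIZER.Canonicalize(mol)
    except Exception:  # pragma: no cover - rdkit internal failure
        return StandardizationResult("rejected", RejectReason.UNPARSEABLE)

    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= ALLOWED_ELEMENTS:
        return StandardizationResult("rejected", RejectReason.NON_ORGANIC)

    if mol.GetNumHeavyAtoms() < 3:
        return StandardizationResult("rejected", RejectReason.TOO_SMALL)

    return StandardizationResult("kept", standardized_structure=Chem.MolToSmiles(mol))


def resolve_duplicates(
    records: Iterable[tuple[str, str, int]],
) -> list[tuple[str, str, int]]:
    """Collapse replicate measurements per (structure key, endpoint).

    All labels agree → keep a single record; labels conflict → discard the
    whole group.  Output order follows first appearance of each key.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    for key, endpoint, label in records:
        k = (key, endpoint)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(int(label))
    out = []
    for k in order:
        labels = set(groups[k])
        if len(labels) == 1:
            out.append((k[0], k[1], labels.pop()))
    return out


@dataclass
class RejectionLogEntry:
    compound_id: str
    structure: str
    endpoint: str | None
    reason: str


def prepare_activity_matrix(
    raw_records: Sequence[tuple[str, str, str, int]],
    excluded_endpoints: Iterable[str] = (),
    canonical_tautomer: bool = True,
) -> tuple[ActivityMatrix, list[RejectionLogEntry]]:
    """Standardise raw (compound_id, smiles, endpoint, label) records into an
    ActivityMatrix plus a complete rejection log.

    Duplicate resolution runs twice — on the raw structure key and again on
    the standardised key — because standardisation can merge previously
    distinct structures.  Every input record ends up either in the matrix or
    in the log, never both, never neither.
    """
    excluded = set(excluded_endpoints)
    log: list[RejectionLogEntry] = []

    surviving: list[tuple[str, str, str, int]] = []  # (raw_key, cid, endpoint, label)
    for cid, smiles, endpoint, label in raw_records:
        if endpoint in excluded:
            log.append(RejectionLogEntry(cid, smiles, endpoint, "excluded_endpoint"))
        else:
            surviving.append((smiles, cid, endpoint, int(label)))

    # pre-standardisation duplicate resolution on the raw structure string
    kept_keys = set(
        resolve_duplicates([(k, e, l) for k, _, e, l in surviving])
    )
    deduped: list[tuple[str, str, str, int]] = []
    seen: set[tuple[str, str]] = set()
    for k, cid, e, l in surviving:
        if (k, e, l) not in kept_keys:
            log.append(RejectionLogEntry(cid, k, e, "duplicate_conflict_or_replicate"))
        elif (k, e) in seen:
            log.append(RejectionLogEntry(cid, k, e, "duplicate_conflict_or_replicate"))
        else:
            seen.add((k, e))
            deduped.append((k, cid, e, l))

    # standardisation
    std_cache: dict[str, StandardizationResult] = {}
    standardized: list[tuple[str, str, str, int]] = []  # (std_key, cid, endpoint, label)
    for raw, cid, e, l in deduped:
        if raw not in std_cache:
            std_cache[raw] = standardize_molecule(raw, canonical_tautomer=canonical_tautomer)
        res = std_cache[raw]
        if not res.kept:
            log.append(RejectionLogEntry(cid, raw, e, res.reason.value))
        else:
            standardized.append((res.standardized_structure, cid, e, l))

    # post-standardisation duplicate resolution on the canonical key
    kept_keys2 = set(resolve_duplicates([(k, e, l) for k, _, e, l in standardized]))
    seen2: set[tuple[str, str]] = set()
    rows: list[dict] = []
    structures: dict[str, str] = {}
    for k, cid, e, l in standardized:
        if (k, e, l) not in kept_keys2 or (k, e) in seen2:
            log.append(RejectionLogEntry(cid, k, e, "duplicate_conflict_or_replicate"))
            continue
        seen2.add((k, e))
        structures[k] = k
        rows.append({"compound_id": k, "endpoint": e, "label": l})

    if not rows:
        logger.warning("no records survived standardisation; matrix is empty")
        values = pd.DataFrame(columns=["compound_id", "endpoint", "label"])
        return ActivityMatrix([], [], values, {}), log

    values = pd.DataFrame(rows)
    matrix = ActivityMatrix(
        compounds=sorted(values["compound_id"].unique()),
        endpoints=sorted(values["endpoint"].unique()),
        values=values,
        structures=structures,
    )
    return matrix, log
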