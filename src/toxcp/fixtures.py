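"""Deterministic synthetic data generators.

Everything in the package is testable without external downloads:

* an enumerated combinatorial library of small organic molecules
  (substituted benzenes, heterocycles, alkanes) with *planted*
  structure–activity rules — a SMARTS pattern decides the true class,
  optionally flipped by Bernoulli label noise;
* abstract exchangeable feature/label datasets (two-component Gaussian
  mixture, i.i.d. rows) satisfying exactly the exchangeability premise of
  conformal validity;
* sparse synthetic activity matrices with per-endpoint planted rules and a
  controllable missingness rate, emulating high-throughput screening
  hitcall tables.

Scaffolds are enumerated, not randomly grown, so every emitted SMILES is
valid and already in standardised canonical form; randomness affects only
selection, labels and missingness masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemprep import ActivityMatrix, standardize_molecule

# 1-slot and 2-slot templates; {0}/{1} are substitution sites.  "()" left by
# an empty substituent is stripped before parsing.
_TEMPLATES_1 = (
    "c1ccc({0})cc1",          # monosubstituted benzene
    "c1ccnc({0})c1",          # 2-substituted pyridine
    "c1ccc({0})o1",           # 2-substituted furan
    "C1CCC({0})CC1",          # substituted cyclohexane
    "CCCC({0})C",             # branched pentane
    "C({0})C1CO1",            # substituted epoxide
)
_TEMPLATES_2 = (
    "c1cc({0})ccc1{1}",       # 1,4-disubstituted benzene
    "c1cc({0})cc({1})c1",     # 1,3-disubstituted benzene
    "c1ccc({0})c({1})c1",     # 1,2-disubstituted benzene
    "c1cc({0})cnc1{1}",       # disubstituted pyridine
    "c1cc({0})co1{1}",        # disubstituted furan
    "CC({0})CCC({1})C",       # disubstituted hexane
    "c2ccc1cc({0})c({1})cc1c2",  # disubstituted naphthalene
)
_SUBSTITUENTS = (
    "", "F", "Cl", "Br", "I", "C", "CC", "C(C)C", "O", "OC", "N",
    "[N+](=O)[O-]", "SC", "C=O", "C#N", "C(=O)O", "C(=O)C", "CCl",
    "C(F)(F)F", "CO",
)


@dataclass(frozen=True)
class PlantedRule:
    """A planted structure–activity rule: active ⇔ the molecule contains
    ``smarts``, with each label independently flipped with probability
    ``label_noise`` (< 0.5 so the rule stays learnable)."""

    smarts: str = "[c][N+](=O)[O-]"  # nitroaromatic
    label_noise: float = 0.0
    active_fraction_target: float | None = None

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"invalid rule SMARTS: {self.smarts!r}")

    def matches(self, structure: str) -> bool:
        mol = Chem.MolFromSmiles(structure)
        return mol is not None and mol.HasSubstructMatch(Chem.MolFromSmarts(self.smarts))


@lru_cache(maxsize=1)
def molecule_library() -> tuple[str, ...]:
    """The full enumerated scaffold library: standardised canonical SMILES,
    deduplicated, sorted.  Every member survives standardisation unchanged
    by construction (the library stores the standardised form)."""
    out: set[str] = set()
    candidates: list[str] = []
    for t in _TEMPLATES_1:
        for s in _SUBSTITUENTS:
            candidates.append(t.format(s).replace("()", ""))
    for t in _TEMPLATES_2:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                candidates.append(t.format(s1, s2).replace("()", ""))
    for smi in candidates:
        if Chem.MolFromSmiles(smi) is None:
            continue
        res = standardize_molecule(smi)
        if res.kept:
            out.add(res.standardized_structure)
    return tuple(sorted(out))


def generate_molecule_dataset(
    n: int, planted_rule: PlantedRule | None = None, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Draw ``n`` molecules from the enumerated library with labels from the
    planted rule XOR Bernoulli(label_noise).

    With ``active_fraction_target`` set, actives (rule matches, before
    noise) are drawn to hit that fraction; otherwise selection is uniform.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    rule = planted_rule or PlantedRule()
    lib = molecule_library()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    if rule.active_fraction_target is None:
        if n > len(lib):
            raise ValueError(f"n={n} exceeds library capacity {len(lib)}")
        structures = list(rng.choice(lib, size=n, replace=False))
    else:
        pos = [s for s in lib if rule.matches(s)]
        neg = [s for s in lib if not rule.matches(s)]
        n_pos = int(round(n * rule.active_fraction_target))
        n_neg = n - n_pos
        if n_pos > len(pos) or n_neg > len(neg):
            raise ValueError(
                f"capacity exceeded: library holds {len(pos)} rule-matching and "
                f"{len(neg)} non-matching molecules; requested {n_pos}/{n_neg}"
            )
        structures = list(rng.choice(pos, size=n_pos, replace=False)) + list(
            rng.choice(neg, size=n_neg, replace=False)
        )
        rng.shuffle(structures)

    truth = np.array([rule.matches(s) for s in structures], dtype=int)
    flips = rng.random(n) < rule.label_noise
    labels = truth ^ flips.astype(int)
    return structures, labels


def generate_feature_dataset(
    n: int, dim: int = 20, class_separation: float = 2.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable two-class Gaussian mixture: i.i.d. rows, labels
    Bernoulli(1/2), unit-variance noise, class means ``class_separation``
    apart in Euclidean distance (spread evenly over all dimensions)."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    y = rng.integers(0, 2, size=n)
    shift = class_separation / np.sqrt(dim)
    X = rng.normal(size=(n, dim)) + y[:, None] * shift
    return X, y


#: Per-endpoint rule SMARTS cycled by generate_activity_matrix.
ENDPOINT_RULE_SMARTS = (
    "[c][N+](=O)[O-]",   # nitroaromatic
    "c[F,Cl,Br,I]",      # halogenated aromatic
    "[#6][SX2][#6]",     # thioether
    "[CX3H1]=[OX1]",     # aldehyde
    "C(=O)O",            # carboxyl
    "[OX2r3]1[#6r3][#6r3]1",  # epoxide
)


def generate_activity_matrix(
    n_compounds: int,
    n_endpoints: int,
    sparsity: float = 0.3,
    seed: int = 0,
    label_noise: float = 0.1,
    min_active: int = 300,
    min_inactive: int = 300,
) -> tuple[ActivityMatrix, dict[str, bool]]:
    """Sparse synthetic hitcall matrix with per-endpoint planted rules.

    Each endpoint e uses rule SMARTS ``ENDPOINT_RULE_SMARTS[e mod len]``;
    a fraction ``sparsity`` of (compound, endpoint) cells is masked as
    never-tested.  Returns the matrix plus an eligibility flag per endpoint
    (class counts reaching ``min_active``/``min_inactive``)."""
    if not (0 <= sparsity <= 1):
        raise ValueError("sparsity must lie in [0, 1]")
    lib = molecule_library()
    if n_compounds > len(lib):
        raise ValueError(f"n_compounds={n_compounds} exceeds library capacity {len(lib)}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    structures = list(rng.choice(lib, size=n_compounds, replace=False))
    ids = [f"c{i:05d}" for i in range(n_compounds)]
    endpoints = [f"ep{j:03d}" for j in range(n_endpoints)]

    rows = []
    for j, ep in enumerate(endpoints):
        rule = PlantedRule(
            smarts=ENDPOINT_RULE_SMARTS[j % len(ENDPOINT_RULE_SMARTS)],
            label_noise=label_noise,
        )
        truth = np.array([rule.matches(s) for s in structures], dtype=int)
        flips = (rng.random(n_compounds) < label_noise).astype(int)
        labels = truth ^ flips
        tested = rng.random(n_compounds) >= sparsity
        for i in np.flatnonzero(tested):
            rows.append({"compound_id": ids[i], "endpoint": ep, "label": int(labels[i])})

    values = pd.DataFrame(rows, columns=["compound_id", "endpoint", "label"])
    matrix = ActivityMatrix(
        compounds=sorted(values["compound_id"].unique()) if len(values) else [],
        endpoints=sorted(values["endpoint"].unique()) if len(values) else [],
        values=values,
        structures=dict(zip(ids, structures)),
    )
    eligibility = {}
    for ep in endpoints:
        n_act, n_inact = matrix.class_counts(ep)
        eligibility[ep] = n_act >= min_active and n_inact >= min_inactive
    return matrix, eligibility
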