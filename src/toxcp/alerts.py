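"""SMARTS structural-alert screening.

An alert library associates SMARTS substructure patterns with literature-
annotated toxic effects.  Screening a query molecule reports every alert
that matches, with atom-index tuples for each symmetry-distinct match so a
front end can highlight the offending moiety.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlertDefinition:
    alert_id: str
    smarts: str
    effect: str
    source: str = ""

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:  # pragma: no cover - guarded at load time
            raise ValueError(f"invalid SMARTS for alert {self.alert_id}: {self.smarts}")
        return patt


@dataclass(frozen=True)
class AlertHit:
    alert_id: str
    effect: str
    matched_atom_indices: tuple[tuple[int, ...], ...]


def _build_library(rows: list[dict]) -> list[AlertDefinition]:
    defs: list[AlertDefinition] = []
    seen: set[str] = set()
    for row in rows:
        aid = str(row["alert_id"])
        if aid in seen:
            raise ValueError(f"duplicate alert_id {aid!r} in library")
        seen.add(aid)
        if Chem.MolFromSmarts(str(row["smarts"])) is None:
            logger.warning("skipping alert %s: unparseable SMARTS %r", aid, row["smarts"])
            continue
        defs.append(AlertDefinition(aid, str(row["smarts"]), str(row.get("effect", "")),
                                    str(row.get("source", ""))))
    if not defs:
        raise ValueError("alert library contains no valid alerts")
    return defs


def load_alert_library(path: str | Path) -> list[AlertDefinition]:
    """Load alerts from TSV (columns alert_id, smarts, effect, source) or a
    JSON list of objects.  Rows with unparseable SMARTS are skipped with a
    logged warning; duplicate alert ids are an error."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        lines = [l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")]
        header = lines[0].split("\t")
        rows = [dict(zip(header, l.split("\t"))) for l in lines[1:]]
    return _build_library(rows)


def builtin_alert_library() -> list[AlertDefinition]:
    """The small curated example library shipped with the package (a
    synthetic stand-in for full literature alert collections)."""
    with resources.as_file(resources.files("toxcp.data") / "alerts_example.tsv") as p:
        return load_alert_library(p)


def screen_molecule(structure: str, library: list[AlertDefinition]) -> list[AlertHit]:
    """All alerts matching the query as a substructure, each with every
    symmetry-distinct atom-index tuple (overlapping matches allowed)."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable molecule: {structure!r}")
    hits: list[AlertHit] = []
    for alert in library:
        matches = mol.GetSubstructMatches(alert.pattern(), uniquify=True)
        if matches:
            hits.append(AlertHit(alert.alert_id, alert.effect, tuple(matches)))
    return hits
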