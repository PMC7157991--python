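"""End-to-end orchestration: per-endpoint model registry and the combined
toxicity-profile report.

A registry holds one cross-validated conformal model per *eligible*
endpoint — an endpoint qualifies only if enough compounds were measured in
both classes (default 300 active and 300 inactive), since conformal
calibration needs well-populated mondrian class lists.  Profiling a query
compound invokes three prongs: per-endpoint conformal prediction,
structural-alert screening, and similarity-based read-across, merged into
one report with full provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from . import __version__
from .alerts import AlertDefinition, screen_molecule
from .chemprep import ActivityMatrix, standardize_molecule
from .conformal import CrossValidatedConformal, credibility_confidence, prediction_set
from .evaluate import efficiency, validity
from .features import MoleculeFeaturizer, fingerprint
from .readacross import extract_activities, rank_similar

logger = logging.getLogger(__name__)


def select_eligible_endpoints(
    activity_matrix: ActivityMatrix,
    min_active: int = 300,
    min_inactive: int = 300,
) -> list[str]:
    """Endpoints whose class counts reach the registration thresholds."""
    out = []
    for ep in activity_matrix.endpoints:
        n_act, n_inact = activity_matrix.class_counts(ep)
        if n_act >= min_active and n_inact >= min_inactive:
            out.append(ep)
    return out


@dataclass
class RegistryEntry:
    endpoint: str
    model: CrossValidatedConformal
    n_active: int
    n_inactive: int
    validity_at_02: float
    efficiency_at_02: float


@dataclass
class ModelRegistry:
    featurizer: MoleculeFeaturizer
    entries: dict[str, RegistryEntry]
    config: dict = field(default_factory=dict)

    @property
    def endpoints(self) -> list[str]:
        return sorted(self.entries)

    def summary(self) -> dict:
        return {
            ep: {
                "n_active": e.n_active,
                "n_inactive": e.n_inactive,
                "validity_at_0.2": e.validity_at_02,
                "efficiency_at_0.2": e.efficiency_at_02,
            }
            for ep, e in self.entries.items()
        }

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.featurizer.save(directory / "featurizer.json")
        (directory / "registry.json").write_text(json.dumps({
            "config": self.config,
            "summary": self.summary(),
        }, indent=2, sort_keys=True))
        for ep, entry in self.entries.items():
            joblib.dump(entry, directory / f"model_{ep}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelRegistry":
        directory = Path(directory)
        meta = json.loads((directory / "registry.json").read_text())
        featurizer = MoleculeFeaturizer.load(directory / "featurizer.json")
        entries = {}
        for p in sorted(directory.glob("model_*.joblib")):
            entry: RegistryEntry = joblib.load(p)
            entries[entry.endpoint] = entry
        return cls(featurizer, entries, meta["config"])


def train_registry(
    activity_matrix: ActivityMatrix,
    variant: str = "normalised_balanced",
    min_active: int = 300,
    min_inactive: int = 300,
    random_state: int | None = None,
    **conformal_kwargs,
) -> ModelRegistry:
    """One cross-validated conformal model per eligible endpoint.

    The featurizer is fitted once on the full standardised corpus
    (fingerprint-only for the original variant, fingerprint+physchem
    otherwise).  Per-endpoint training failures are logged and skipped.
    """
    structures = activity_matrix.structures
    corpus = [structures[c] for c in activity_matrix.compounds]
    if not corpus:
        raise ValueError("empty activity matrix")
    mode = "fingerprint_only" if variant == "original" else "fingerprint_plus_physchem"
    featurizer = MoleculeFeaturizer(mode=mode).fit(corpus)
    feats = {
        cid: f
        for cid, f in zip(
            activity_matrix.compounds,
            featurizer.transform([structures[c] for c in activity_matrix.compounds]),
        )
    }

    ss = np.random.SeedSequence(random_state)
    rng = np.random.Generator(np.random.PCG64(ss))
    entries: dict[str, RegistryEntry] = {}
    eligible = select_eligible_endpoints(activity_matrix, min_active, min_inactive)
    for ep in eligible:
        sub = activity_matrix.endpoint_data(ep)
        X = np.stack([feats[c] for c in sub["compound_id"]])
        y = sub["label"].to_numpy(dtype=int)
        model = CrossValidatedConformal(
            variant=variant,
            random_state=int(rng.integers(2**31)),
            **conformal_kwargs,
        )
        try:
            model.fit(X, y)
        except Exception as exc:
            logger.warning("skipping endpoint %s: %s", ep, exc)
            continue
        n_act, n_inact = activity_matrix.class_counts(ep)
        entries[ep] = RegistryEntry(
            endpoint=ep,
            model=model,
            n_active=n_act,
            n_inactive=n_inact,
            validity_at_02=validity(model.test_p_values_, model.test_y_, 0.2),
            efficiency_at_02=efficiency(model.test_p_values_, 0.2),
        )
    config = {
        "variant": variant,
        "min_active": min_active,
        "min_inactive": min_inactive,
        "random_state": random_state,
        **{k: v for k, v in conformal_kwargs.items()},
    }
    return ModelRegistry(featurizer, entries, config)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def profile_compounds(
    query_structures: list[str],
    registry: ModelRegistry,
    alert_library: list[AlertDefinition],
    reference_matrix: ActivityMatrix,
    epsilon: float = 0.2,
    top_n_similar: int = 4,
    endpoint_families: dict[str, str] | None = None,
    compute_mcs: bool = True,
) -> dict:
    """Run all three prongs for each query and emit the combined report.

    Queries failing standardisation appear in the report with their
    rejection reason instead of crashing the run.  The report is a pure
    function of (inputs, registry, epsilon): reruns are byte-identical.
    """
    families = endpoint_families or {}
    ref_corpus = dict(reference_matrix.structures)
    ref_fps = {cid: fingerprint(s) for cid, s in ref_corpus.items()}

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "epsilon": epsilon,
            "registry_config": registry.config,
            "config_hash": _config_hash(registry.config),
            "n_alerts_in_library": len(alert_library),
        },
        "queries": [],
    }

    for raw in query_structures:
        entry: dict = {"input_structure": raw}
        std = standardize_molecule(raw)
        if not std.kept:
            entry["status"] = "rejected"
            entry["rejection_reason"] = std.reason.value
            report["queries"].append(entry)
            continue
        smi = std.standardized_structure
        entry["status"] = "ok"
        entry["standardized_structure"] = smi

        # prong 1: conformal prediction per registered endpoint
        X = registry.featurizer.transform([smi])
        predictions = {}
        for ep in registry.endpoints:
            p0, p1 = registry.entries[ep].model.predict_p(X)[0]
            cred, conf = credibility_confidence((p0, p1))
            predictions[ep] = {
                "family": families.get(ep, "unknown"),
                "p0": round(float(p0), 6),
                "p1": round(float(p1), 6),
                "prediction_set": sorted(prediction_set((p0, p1), epsilon)),
                "credibility": round(cred, 6),
                "confidence": round(conf, 6),
            }
        entry["conformal_predictions"] = predictions

        # prong 2: structural alerts
        entry["alerts"] = [
            {
                "alert_id": h.alert_id,
                "effect": h.effect,
                "matched_atom_indices": [list(m) for m in h.matched_atom_indices],
            }
            for h in screen_molecule(smi, alert_library)
        ]

        # prong 3: similarity search + read-across
        if ref_corpus:
            hits = rank_similar(
                smi, ref_corpus, top_n=top_n_similar,
                reference_fingerprints=ref_fps, compute_mcs=compute_mcs,
            )
            activities = extract_activities([h.compound_id for h in hits], reference_matrix)
            entry["similar_compounds"] = [
                {
                    "compound_id": h.compound_id,
                    "structure": ref_corpus[h.compound_id],
                    "tanimoto": round(h.tanimoto, 6),
                    "rank": h.rank,
                    "mcs_smarts": h.mcs_smarts,
                    "mcs_atom_count": h.mcs_atom_count,
                    "read_across": activities[h.compound_id],
                }
                for h in hits
            ]
        else:
            entry["similar_compounds"] = []
        report["queries"].append(entry)

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=str)
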