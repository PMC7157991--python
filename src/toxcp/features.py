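"""Molecular feature vectors for similarity search and conformal models.

Two descriptor modes mirror the model variants:

* ``fingerprint_only`` — the raw 1191-bit binary concatenation of the 167
  MACCS keys and a 1024-bit Morgan fingerprint (radius 3).  Used for
  similarity search and the plain conformal model; no corpus-dependent
  state.
* ``fingerprint_plus_physchem`` — the same bits variance-filtered at 0.01,
  concatenated with z-scored RDKit physicochemical descriptors variance-
  filtered at 0.001.  Masks and normalisation parameters are learned once
  on the standardised training corpus and frozen.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MACCS_BITS = 167
DEFAULT_MORGAN_BITS = 1024
DEFAULT_MORGAN_RADIUS = 3
FINGERPRINT_LENGTH = MACCS_BITS + DEFAULT_MORGAN_BITS  # 1191

#: Frozen, sorted list of RDKit 2-D physicochemical descriptor names.
PHYSCHEM_NAMES: tuple[str, ...] = tuple(sorted(n for n, _ in Descriptors.descList))


def _mol(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return mol


def fingerprint(
    structure: str,
    morgan_radius: int = DEFAULT_MORGAN_RADIUS,
    morgan_bits: int = DEFAULT_MORGAN_BITS,
) -> np.ndarray:
    """Binary [MACCS ‖ Morgan] fingerprint; length 167 + morgan_bits (1191
    by default) for any parseable molecule."""
    mol = _mol(structure)
    maccs = np.zeros(MACCS_BITS, dtype=np.uint8)
    fp = MACCSkeys.GenMACCSKeys(mol)
    maccs[list(fp.GetOnBits())] = 1
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=morgan_radius, fpSize=morgan_bits)
    morgan = np.zeros(morgan_bits, dtype=np.uint8)
    morgan[list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return np.concatenate([maccs, morgan])


def physchem_descriptors(structure: str) -> np.ndarray:
    """All RDKit 2-D physicochemical descriptors in the frozen name order.
    Values that fail to compute or are non-finite come back as NaN; the
    featurizer imputes them with fit-corpus means."""
    mol = _mol(structure)
    values = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
    arr = np.array([values[n] for n in PHYSCHEM_NAMES], dtype=np.float64)
    arr[~np.isfinite(arr)] = np.nan
    return arr


class MoleculeFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from SMILES lists to model-ready feature matrices.

    Parameters
    ----------
    mode : {"fingerprint_only", "fingerprint_plus_physchem"}
        ``fingerprint_only`` emits the raw 1191-bit fingerprint unchanged
        (fit learns nothing, masks are all-true).  The physchem mode learns
        a binary variance mask, per-descriptor z-score parameters and a
        post-normalisation physchem variance mask from the fit corpus.
    morgan_radius, morgan_bits : Morgan fingerprint geometry.
    binary_variance_threshold : minimum variance for a fingerprint bit to
        survive (applies only in physchem mode).
    physchem_variance_threshold : minimum post-normalisation variance for a
        physchem descriptor to survive.

    Attributes (after ``fit``)
    --------------------------
    binary_keep_mask_, physchem_keep_mask_ : boolean masks.
    physchem_mean_, physchem_scale_ : z-score parameters on the fit corpus.
    output_dim_ : final feature-vector length.
    """

    def __init__(
        self,
        mode: str = "fingerprint_only",
        morgan_radius: int = DEFAULT_MORGAN_RADIUS,
        morgan_bits: int = DEFAULT_MORGAN_BITS,
        binary_variance_threshold: float = 0.01,
        physchem_variance_threshold: float = 0.001,
    ):
        self.mode = mode
        self.morgan_radius = morgan_radius
        self.morgan_bits = morgan_bits
        self.binary_variance_threshold = binary_variance_threshold
        self.physchem_variance_threshold = physchem_variance_threshold

    @property
    def _n_bits(self) -> int:
        return MACCS_BITS + self.morgan_bits

    def _validate(self) -> None:
        if self.mode not in ("fingerprint_only", "fingerprint_plus_physchem"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.binary_variance_threshold < 0 or self.physchem_variance_threshold < 0:
            raise ValueError("variance thresholds must be >= 0")
        if self.morgan_bits <= 0 or self.morgan_bits & (self.morgan_bits - 1):
            raise ValueError("morgan_bits must be a positive power of two")

    def _fingerprints(self, structures) -> np.ndarray:
        return np.stack([
            fingerprint(s, self.morgan_radius, self.morgan_bits) for s in structures
        ])

    def fit(self, X, y=None) -> "MoleculeFeaturizer":
        """Learn masks and normalisation on a corpus of SMILES strings."""
        self._validate()
        structures = list(X)
        if not structures:
            raise ValueError("empty corpus")

        if self.mode == "fingerprint_only":
            self.binary_keep_mask_ = np.ones(self._n_bits, dtype=bool)
            self.physchem_keep_mask_ = np.zeros(0, dtype=bool)
            self.physchem_mean_ = np.zeros(0)
            self.physchem_scale_ = np.zeros(0)
            self.output_dim_ = self._n_bits
            return self

        if len(structures) < 2:
            raise ValueError("degenerate corpus: need >= 2 molecules to estimate variances")

        bits = self._fingerprints(structures).astype(np.float64)
        bit_var = bits.var(axis=0)
        self.binary_keep_mask_ = bit_var >= self.binary_variance_threshold
        if not self.binary_keep_mask_.any():
            raise ValueError("degenerate corpus: every fingerprint bit is (near-)constant")

        phys = np.stack([physchem_descriptors(s) for s in structures])
        n_nan = int(np.isnan(phys).sum())
        if n_nan:
            logger.info("imputing %d non-finite physchem values with corpus means", n_nan)
        self.physchem_mean_ = np.nanmean(phys, axis=0)
        self.physchem_mean_ = np.where(np.isfinite(self.physchem_mean_), self.physchem_mean_, 0.0)
        filled = np.where(np.isnan(phys), self.physchem_mean_, phys)
        scale = filled.std(axis=0)
        self.physchem_scale_ = np.where(scale > 0, scale, 1.0)
        z = (filled - self.physchem_mean_) / self.physchem_scale_
        self.physchem_keep_mask_ = z.var(axis=0) >= self.physchem_variance_threshold
        self.output_dim_ = int(self.binary_keep_mask_.sum() + self.physchem_keep_mask_.sum())
        return self

    def transform(self, X) -> np.ndarray:
        """Featurise SMILES with the frozen masks and normalisation.  Novel
        molecules may produce z-scores outside the fit range; no clipping."""
        check_is_fitted(self, "output_dim_")
        structures = list(X)
        bits = self._fingerprints(structures).astype(np.float64)
        if self.mode == "fingerprint_only":
            return bits
        out_bits = bits[:, self.binary_keep_mask_]
        phys = np.stack([physchem_descriptors(s) for s in structures])
        phys = np.where(np.isnan(phys), self.physchem_mean_, phys)
        z = (phys - self.physchem_mean_) / self.physchem_scale_
        return np.hstack([out_bits, z[:, self.physchem_keep_mask_]])

    # -- serialisation ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "output_dim_")
        payload = {
            "format_version": 1,
            "params": self.get_params(),
            "binary_keep_mask": self.binary_keep_mask_.astype(int).tolist(),
            "physchem_keep_mask": self.physchem_keep_mask_.astype(int).tolist(),
            "physchem_mean": self.physchem_mean_.tolist(),
            "physchem_scale": self.physchem_scale_.tolist(),
            "physchem_names": list(PHYSCHEM_NAMES),
            "output_dim": self.output_dim_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MoleculeFeaturizer":
        payload = json.loads(Path(path).read_text())
        est = cls(**payload["params"])
        est.binary_keep_mask_ = np.array(payload["binary_keep_mask"], dtype=bool)
        est.physchem_keep_mask_ = np.array(payload["physchem_keep_mask"], dtype=bool)
        est.physchem_mean_ = np.array(payload["physchem_mean"])
        est.physchem_scale_ = np.array(payload["physchem_scale"])
        est.output_dim_ = payload["output_dim"]
        return est
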