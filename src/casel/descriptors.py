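"""2D molecular descriptors and correlation-based feature pruning.

The baseline feature set is a frozen manifest of 118 RDKit 2D physicochemical
descriptors (constitutional, topological, electrotopological-state, charge-
and surface-area descriptors; fragment counts and composite scores excluded).
Freezing the names in source makes descriptor-provider version drift
detectable: a missing or renamed descriptor fails loudly instead of silently
changing the feature space.

Correlated features are pruned with a greedy first-seen scan at a Pearson
correlation threshold: walking the columns in manifest order, a column is
dropped when its |PCC| with any earlier retained column reaches the
threshold.  The retained set therefore satisfies the pairwise bound
|PCC| < threshold, and is deterministic given the column order (a different
order may give a different, equally valid set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _rdkit_descriptors
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator

logger = logging.getLogger(__name__)

#: Frozen baseline manifest: 118 RDKit 2D descriptors, in provider order.
BASELINE_DESCRIPTORS: Tuple[str, ...] = (
    "MaxAbsEStateIndex", "MaxEStateIndex", "MinAbsEStateIndex",
    "MinEStateIndex", "MolWt", "HeavyAtomMolWt", "ExactMolWt",
    "NumValenceElectrons", "NumRadicalElectrons", "MaxPartialCharge",
    "MinPartialCharge", "MaxAbsPartialCharge", "MinAbsPartialCharge",
    "BCUT2D_MWHI", "BCUT2D_MWLOW", "BCUT2D_CHGHI", "BCUT2D_CHGLO",
    "BCUT2D_LOGPHI", "BCUT2D_LOGPLOW", "BCUT2D_MRHI", "BCUT2D_MRLOW",
    "BalabanJ", "BertzCT", "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n",
    "Chi1v", "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
    "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3", "LabuteASA",
    "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13",
    "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
    "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9",
    "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4",
    "SMR_VSA5", "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9",
    "SlogP_VSA1", "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12",
    "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5", "SlogP_VSA6",
    "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9", "TPSA",
    "EState_VSA1", "EState_VSA10", "EState_VSA11", "EState_VSA2",
    "EState_VSA3", "EState_VSA4", "EState_VSA5", "EState_VSA6",
    "EState_VSA7", "EState_VSA8", "EState_VSA9",
    "VSA_EState1", "VSA_EState10", "VSA_EState2", "VSA_EState3",
    "VSA_EState4", "VSA_EState5", "VSA_EState6", "VSA_EState7",
    "VSA_EState8", "VSA_EState9",
    "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumAliphaticRings", "NumAromaticCarbocycles",
    "NumAromaticHeterocycles", "NumAromaticRings", "NumHAcceptors",
    "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumSaturatedRings", "RingCount", "MolLogP", "MolMR",
)

assert len(BASELINE_DESCRIPTORS) == 118


@dataclass
class DescriptorTable:
    """Compound x descriptor matrix with an optional pruning mask.

    ``pruned_mask[j]`` is True when descriptor j has been removed by the
    correlation filter; ``retained_names``/``retained_values`` expose the
    surviving feature space.
    """

    compound_ids: List[str]
    descriptor_names: List[str]
    values: np.ndarray
    pruned_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    pcc_threshold: Optional[float] = None
    failures: Dict[str, List[str]] = field(default_factory=dict)
    constant_columns: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.compound_ids)} compounds x "
                f"{len(self.descriptor_names)} descriptors"
            )
        if self.pruned_mask is None:
            self.pruned_mask = np.zeros(len(self.descriptor_names), dtype=bool)
        self.pruned_mask = np.asarray(self.pruned_mask, dtype=bool)

    @property
    def retained_names(self) -> List[str]:
        return [n for n, p in zip(self.descriptor_names, self.pruned_mask) if not p]

    @property
    def retained_values(self) -> np.ndarray:
        return self.values[:, ~self.pruned_mask]

    def to_frame(self, retained_only: bool = False) -> pd.DataFrame:
        if retained_only:
            return pd.DataFrame(
                self.retained_values, index=self.compound_ids,
                columns=self.retained_names,
            )
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    def feature_matrix(self, compound_ids: Sequence[str]) -> np.ndarray:
        """Retained-descriptor rows for the requested compounds, in order."""
        index = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in compound_ids if c not in index]
        if missing:
            raise KeyError(f"compounds without descriptors: {missing[:5]}")
        rows = [index[c] for c in compound_ids]
        return self.retained_values[rows]


def compute_descriptors(
    compounds: Mapping[str, str] | Sequence[Tuple[str, str]],
    descriptor_set: Optional[Sequence[str]] = None,
) -> DescriptorTable:
    """Compute named 2D descriptors for a set of compounds.

    ``compounds`` maps compound id -> SMILES.  Unknown descriptor names are a
    hard error listing what is available; a failing descriptor yields NaN for
    that compound and the compound is listed in ``table.failures``.
    """
    if descriptor_set is None:
        descriptor_set = BASELINE_DESCRIPTORS
    available = {n for n, _ in _rdkit_descriptors._descList}
    unknown = [n for n in descriptor_set if n not in available]
    if unknown:
        raise ValueError(
            f"unknown descriptors {unknown}; available: {sorted(available)}"
        )
    items = list(compounds.items()) if isinstance(compounds, Mapping) else list(compounds)
    calculator = MolecularDescriptorCalculator(list(descriptor_set))

    ids: List[str] = []
    rows: List[np.ndarray] = []
    failures: Dict[str, List[str]] = {}
    for compound_id, smiles in items:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures[compound_id] = ["<unparseable SMILES>"]
            row = np.full(len(descriptor_set), np.nan)
        else:
            row = np.asarray(calculator.CalcDescriptors(mol), dtype=float)
            bad = np.flatnonzero(~np.isfinite(row))
            if bad.size:
                failures[compound_id] = [descriptor_set[j] for j in bad]
                row[bad] = np.nan
        ids.append(compound_id)
        rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, len(descriptor_set)))
    if failures:
        logger.warning("descriptor failures for %d compounds", len(failures))
    return DescriptorTable(
        compound_ids=ids,
        descriptor_names=list(descriptor_set),
        values=values,
        failures=failures,
    )


def drop_failed_compounds(table: DescriptorTable) -> DescriptorTable:
    """Remove compounds with any missing descriptor value (reported, not imputed)."""
    keep = ~np.isnan(table.values).any(axis=1)
    return DescriptorTable(
        compound_ids=[c for c, k in zip(table.compound_ids, keep) if k],
        descriptor_names=list(table.descriptor_names),
        values=table.values[keep],
        pruned_mask=table.pruned_mask.copy(),
        pcc_threshold=table.pcc_threshold,
        failures=table.failures,
        constant_columns=list(table.constant_columns),
    )


def filter_correlated(
    table: DescriptorTable, pcc_threshold: Optional[float]
) -> DescriptorTable:
    """Prune correlated descriptors at |PCC| >= threshold (greedy, first kept).

    ``None`` threshold returns an unpruned copy (the baseline feature set).
    Constant columns correlate with nothing; they are retained and reported
    in ``constant_columns``.  Missing values must be handled first (see
    :func:`drop_failed_compounds`).
    """
    if pcc_threshold is None:
        return DescriptorTable(
            compound_ids=list(table.compound_ids),
            descriptor_names=list(table.descriptor_names),
            values=table.values.copy(),
            pcc_threshold=None,
            failures=table.failures,
        )
    if not 0 < pcc_threshold <= 1:
        raise ValueError(f"pcc_threshold must be in (0, 1], got {pcc_threshold}")
    if np.isnan(table.values).any():
        raise ValueError(
            "descriptor matrix contains missing values; drop or impute first"
        )
    values = table.values
    n_cols = values.shape[1]
    sd = values.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False) if n_cols > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns: undefined -> 0

    pruned = np.zeros(n_cols, dtype=bool)
    kept: List[int] = []
    for j in range(n_cols):
        if any(abs(corr[j, i]) >= pcc_threshold for i in kept):
            pruned[j] = True
        else:
            kept.append(j)
    constant_names = [table.descriptor_names[j] for j in np.flatnonzero(constant)]
    if constant_names:
        logger.warning("constant descriptor columns retained: %s", constant_names)
    return DescriptorTable(
        compound_ids=list(table.compound_ids),
        descriptor_names=list(table.descriptor_names),
        values=values.copy(),
        pruned_mask=pruned,
        pcc_threshold=pcc_threshold,
        failures=table.failures,
        constant_columns=constant_names,
    )


def manifest(table: DescriptorTable) -> Dict[str, object]:
    """Provenance manifest: descriptor names, threshold, pruned names."""
    return {
        "descriptor_names": list(table.descriptor_names),
        "pcc_threshold": table.pcc_threshold,
        "n_descriptors": len(table.descriptor_names),
        "n_retained": len(table.retained_names),
        "pruned_names": [
            n for n, p in zip(table.descriptor_names, table.pruned_mask) if p
        ],
        "constant_columns": list(table.constant_columns),
        "failed_compounds": sorted(table.failures),
    }
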