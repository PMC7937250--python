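"""Curation of ChEMBL-style bioactivity exports.

Raw activity exports carry one row per measurement (compound x target x
endpoint x relation x value).  Curation reduces them to one activity value
per compound per isoform:

* keep only Ki / IC50 records in nM with relation "=" (certain) or ">"
  (right-censored, automatically treated as inactive);
* keep only molecules bearing a primary sulfonamide zinc-binding group
  (-SO2NH2 on carbon), the canonical warhead of carbonic anhydrase
  inhibitors;
* merge replicate measurements: a group is kept with its mean when the
  spread is small (SD < 20% of the mean); a noisy group with more than five
  records falls back to the mode of the reported values; a noisy small group
  is discarded as unreliable.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Canonical isoform identifiers used throughout the package.
ISOFORMS: Tuple[str, ...] = ("hCA_II", "hCA_IX", "hCA_XII")

#: ChEMBL target ids of the three isoforms.
DEFAULT_TARGET_MAP: Dict[str, str] = {
    "CHEMBL205": "hCA_II",
    "CHEMBL3594": "hCA_IX",
    "CHEMBL3242": "hCA_XII",
}

#: Default column mapping, matching flat ChEMBL activity exports.
DEFAULT_COLUMNS: Dict[str, str] = {
    "compound_id": "molecule_chembl_id",
    "smiles": "canonical_smiles",
    "endpoint_type": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "units": "standard_units",
    "target_id": "target_chembl_id",
}

ALLOWED_ENDPOINTS: Tuple[str, ...] = ("Ki", "IC50")
ALLOWED_RELATIONS: Tuple[str, ...] = ("=", ">")

#: Primary sulfonamide zinc-binding group: tetravalent S with two
#: double-bonded oxygens, bound to carbon, carrying an NH2 nitrogen.
PRIMARY_SULFONAMIDE_SMARTS = "[#6][SX4](=[OX1])(=[OX1])[NX3H2]"
_PRIMARY_SULFONAMIDE = Chem.MolFromSmarts(PRIMARY_SULFONAMIDE_SMARTS)

#: Relative-spread threshold of the replicate-merging rule.
SD_FRACTION = 0.20
#: Groups noisier than SD_FRACTION are rescued by the mode only above this n.
MODE_MIN_RECORDS = 5


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement."""

    compound_id: str
    smiles: str
    target_id: str
    endpoint_type: str  # "Ki", "IC50" or the raw text for anything else
    relation: str       # "=", ">" or the raw text for anything else
    value: float        # nM when units == "nM"
    units: str

    @property
    def censored(self) -> bool:
        """True for ">" records: the value is a lower bound (inactive)."""
        return self.relation == ">"


@dataclass(frozen=True)
class CompoundActivity:
    """One curated activity value per compound per isoform."""

    compound_id: str
    smiles: str
    isoform: str
    activity_nM: float
    n_records: int
    merge_rule: str            # "single" | "mean_kept" | "mode_replaced"
    censored: bool             # derived solely from ">" records
    any_censored: bool = False # at least one member record was censored


@dataclass
class CurationReport:
    """Counts of records removed at each curation step."""

    n_input: int = 0
    n_malformed: int = 0
    n_removed_filter: int = 0
    n_removed_zbg: int = 0
    n_unparseable_smiles: int = 0
    n_groups: int = 0
    n_groups_discarded: int = 0
    n_compound_activities: int = 0
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {k: getattr(self, k) for k in (
            "n_input", "n_malformed", "n_removed_filter", "n_removed_zbg",
            "n_unparseable_smiles", "n_groups", "n_groups_discarded",
            "n_compound_activities", "warnings",
        )}


def parse_activity_export(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
) -> Tuple[List[ActivityRecord], List[str]]:
    """Parse a flat activity export into records.

    Returns ``(records, warnings)``; malformed rows are excluded but reported
    with their line numbers.  A missing required column is a hard error.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    records: List[ActivityRecord] = []
    warnings: List[str] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        if not header:
            return records, warnings  # empty file -> empty sequence
        for logical, column in colmap.items():
            if column not in header:
                raise ValueError(
                    f"required column {column!r} (for {logical}) missing from "
                    f"{path}; available: {header}"
                )
        for lineno, row in enumerate(reader, start=2):
            raw_value = (row[colmap["value"]] or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                msg = f"line {lineno}: unparseable value {raw_value!r}; row excluded"
                warnings.append(msg)
                logger.warning(msg)
                continue
            records.append(ActivityRecord(
                compound_id=(row[colmap["compound_id"]] or "").strip(),
                smiles=(row[colmap["smiles"]] or "").strip(),
                target_id=(row[colmap["target_id"]] or "").strip(),
                endpoint_type=_normalise_endpoint(row[colmap["endpoint_type"]]),
                relation=(row[colmap["relation"]] or "").strip().strip("'\""),
                value=value,
                units=(row[colmap["units"]] or "").strip(),
            ))
    return records, warnings


def _normalise_endpoint(raw: Optional[str]) -> str:
    text = (raw or "").strip()
    if text.lower() in ("ki", "k_i"):
        return "Ki"
    if text.lower() in ("ic50", "ic_50"):
        return "IC50"
    return text


def filter_records(
    records: Iterable[ActivityRecord],
    allowed_targets: Optional[Sequence[str]] = None,
    allowed_endpoints: Sequence[str] = ALLOWED_ENDPOINTS,
    allowed_relations: Sequence[str] = ALLOWED_RELATIONS,
) -> List[ActivityRecord]:
    """Keep nM records with allowed endpoint, relation and target.

    Pure filter: idempotent, no mutation.  ">" records survive and remain
    flagged censored through :attr:`ActivityRecord.censored`.
    """
    if allowed_targets is None:
        allowed_targets = tuple(DEFAULT_TARGET_MAP)
    targets = set(allowed_targets)
    return [
        r for r in records
        if r.units.lower() == "nm"
        and r.relation in set(allowed_relations)
        and r.endpoint_type in set(allowed_endpoints)
        and r.target_id in targets
        and r.value > 0
    ]


def filter_primary_sulfonamide(
    records: Iterable[ActivityRecord],
) -> Tuple[List[ActivityRecord], List[str]]:
    """Keep records whose molecule bears a primary sulfonamide ZBG.

    SMILES are canonicalised once here for downstream use.  Unparseable
    SMILES are removed with a warning; if *every* SMILES fails to parse the
    column mapping is almost certainly wrong and a hard error is raised.
    """
    records = list(records)
    kept: List[ActivityRecord] = []
    warnings: List[str] = []
    n_unparseable = 0
    canonical_cache: Dict[str, Optional[str]] = {}
    match_cache: Dict[str, bool] = {}
    for r in records:
        if r.smiles not in canonical_cache:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                canonical_cache[r.smiles] = None
                match_cache[r.smiles] = False
            else:
                canonical_cache[r.smiles] = Chem.MolToSmiles(mol)
                match_cache[r.smiles] = mol.HasSubstructMatch(_PRIMARY_SULFONAMIDE)
        canonical = canonical_cache[r.smiles]
        if canonical is None:
            n_unparseable += 1
            msg = f"unparseable SMILES {r.smiles!r} for {r.compound_id}; removed"
            warnings.append(msg)
            logger.warning(msg)
            continue
        if match_cache[r.smiles]:
            kept.append(replace(r, smiles=canonical))
    if records and n_unparseable == len(records):
        raise ValueError(
            "all SMILES failed to parse; check the column mapping of the input"
        )
    return kept, warnings


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def _mode(values: Sequence[float]) -> float:
    """Most frequent value after rounding to 3 significant figures.

    The mode of continuous measurements is taken over 3-significant-figure
    equivalence classes; ties break to the lowest tied value.
    """
    rounded = [_round_sig(v) for v in values]
    counts = Counter(rounded)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def merge_replicates(
    records: Iterable[ActivityRecord],
    target_map: Optional[Mapping[str, str]] = None,
    sd_fraction: float = SD_FRACTION,
    mode_min_records: int = MODE_MIN_RECORDS,
) -> Tuple[List[CompoundActivity], List[Tuple[str, str]]]:
    """Merge replicate measurements into one activity per compound x isoform.

    Decision per group of n records with population SD s and mean m:

    * n == 1           -> keep the value        (merge_rule="single")
    * s <  0.20 m      -> keep the mean         (merge_rule="mean_kept")
    * s >= 0.20 m, n>5 -> keep the mode         (merge_rule="mode_replaced")
    * s >= 0.20 m, n<=5 -> discard the group

    Returns ``(kept, discarded_keys)``; every input group lands in exactly
    one of the two.
    """
    if target_map is None:
        target_map = DEFAULT_TARGET_MAP
    groups: Dict[Tuple[str, str], List[ActivityRecord]] = defaultdict(list)
    for r in records:
        isoform = target_map.get(r.target_id, r.target_id)
        groups[(r.compound_id, isoform)].append(r)

    kept: List[CompoundActivity] = []
    discarded: List[Tuple[str, str]] = []
    for (compound_id, isoform), members in groups.items():
        values = np.array([m.value for m in members], dtype=float)
        all_censored = all(m.censored for m in members)
        any_censored = any(m.censored for m in members)
        smiles = members[0].smiles
        n = len(values)
        if n == 1:
            activity, rule = float(values[0]), "single"
        else:
            mean = float(values.mean())
            sd = float(values.std())  # population SD
            if sd < sd_fraction * mean:
                activity, rule = mean, "mean_kept"
            elif n > mode_min_records:
                activity, rule = _mode(values), "mode_replaced"
            else:
                discarded.append((compound_id, isoform))
                continue
        kept.append(CompoundActivity(
            compound_id=compound_id,
            smiles=smiles,
            isoform=isoform,
            activity_nM=activity,
            n_records=n,
            merge_rule=rule,
            censored=all_censored,
            any_censored=any_censored,
        ))
    return kept, discarded


def curate(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: str = ",",
    target_map: Optional[Mapping[str, str]] = None,
) -> Tuple[pd.DataFrame, CurationReport]:
    """Full curation: parse, filter, ZBG filter, merge.

    Returns the curated-activity table (one row per compound x isoform) and
    a report of what each step removed.
    """
    report = CurationReport()
    records, parse_warnings = parse_activity_export(path, column_map, delimiter)
    report.warnings.extend(parse_warnings)
    report.n_malformed = len(parse_warnings)
    report.n_input = len(records) + report.n_malformed

    allowed_targets = tuple(target_map) if target_map else None
    filtered = filter_records(records, allowed_targets=allowed_targets)
    report.n_removed_filter = len(records) - len(filtered)

    with_zbg, zbg_warnings = filter_primary_sulfonamide(filtered)
    report.warnings.extend(zbg_warnings)
    report.n_unparseable_smiles = len(zbg_warnings)
    report.n_removed_zbg = len(filtered) - len(with_zbg)

    kept, discarded = merge_replicates(with_zbg, target_map=target_map)
    report.n_groups = len(kept) + len(discarded)
    report.n_groups_discarded = len(discarded)
    report.n_compound_activities = len(kept)

    frame = activities_frame(kept)
    return frame, report


def activities_frame(activities: Sequence[CompoundActivity]) -> pd.DataFrame:
    """Curated activities as a tidy table."""
    return pd.DataFrame([{
        "compound_id": a.compound_id,
        "smiles": a.smiles,
        "isoform": a.isoform,
        "activity_nM": a.activity_nM,
        "n_records": a.n_records,
        "merge_rule": a.merge_rule,
        "censored": a.censored,
        "any_censored": a.any_censored,
    } for a in activities])
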