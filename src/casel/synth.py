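"""Synthetic bioactivity studies with ChEMBL-export structure.

The generator emulates the statistical features the analysis pipeline
assumes, so that every stage can be exercised and checked without any
external download:

* a primary-sulfonamide chemotype: compounds are enumerated from a
  benzenesulfonamide / heteroaryl-sulfonamide scaffold grammar, plus a
  configurable fraction of decoys lacking the warhead (to exercise the
  zinc-binding-group filter);
* skewed activity distributions per isoform — many sub-100 nM values, few
  inactives, with isoform-specific location/scale and coverage;
* three *correlated* endpoints: the latent log-activity of each isoform is
  a shared sparse linear function of true computed descriptors (so that
  descriptor-based learners can genuinely recover signal), with small
  per-isoform weight jitter;
* a selective subpopulation whose hCA II activity is shifted up (weaker)
  and whose hCA IX / hCA XII activities are shifted down (more potent);
* replicate records for ~10% of compounds — most consistent (kept with the
  mean by curation), some conflicting small groups (discarded) and some
  conflicting groups of more than five records (rescued via the mode);
* right-censored ">" records injected in the inactive tail.

All randomness flows from one master seed through named substreams, so a
study is fully reproducible from its config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import DEFAULT_COLUMNS, DEFAULT_TARGET_MAP, ISOFORMS, ActivityRecord
from .descriptors import compute_descriptors
from .sampling import fixed_label
from .selectivity import PAIRS, combine_labels

# --------------------------------------------------------------------------
# scaffold grammar

_SUBSTITUENTS: Tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "OC(C)C",
    "N", "NC", "N(C)C", "F", "Cl", "Br", "I", "C(F)(F)F", "OC(F)(F)F",
    "C#N", "[N+](=O)[O-]", "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NC",
    "NC(C)=O", "NC(=O)CC", "S(C)(=O)=O", "SC", "CO", "CCO", "C=C",
    "c9ccccc9", "Cc9ccccc9", "Oc9ccccc9", "OCc9ccccc9", "CN9CCOCC9",
)

_CORES_PLAIN: Tuple[str, ...] = (
    "NS(=O)(=O)c1ccccc1",                 # benzenesulfonamide
    "CC(=O)Nc1nnc(s1)S(N)(=O)=O",         # acetazolamide-like
    "NS(=O)(=O)c1ccc2ccccc2c1",
)

_CORES_1: Tuple[str, ...] = (
    "NS(=O)(=O)c1ccc({R})cc1",
    "NS(=O)(=O)c1cccc({R})c1",
    "NS(=O)(=O)c1ccc({R})s1",             # thiophene-2-sulfonamide
    "NS(=O)(=O)c1nnc({R})s1",             # 1,3,4-thiadiazole
    "NS(=O)(=O)c1ccc({R})o1",
    "NS(=O)(=O)c1ccc2cc({R})ccc2c1",
)

_CORES_2: Tuple[str, ...] = (
    "NS(=O)(=O)c1ccc({R1})c({R2})c1",
    "NS(=O)(=O)c1cc({R1})cc({R2})c1",
)

_DECOY_CORES_1: Tuple[str, ...] = (
    "CNS(=O)(=O)c1ccc({R})cc1",           # secondary sulfonamide: no free NH2
    "OC(=O)c1ccc({R})cc1",                # carboxylic acid warhead
)


@dataclass(frozen=True)
class Compound:
    compound_id: str
    smiles: str
    is_decoy: bool


def _enumerate(templates_plain, templates_1, templates_2) -> List[str]:
    """Enumerate the grammar in fixed order and canonicalise, deduplicated."""
    seen: Dict[str, None] = {}
    raw: List[str] = list(templates_plain)
    for core in templates_1:
        for sub in _SUBSTITUENTS:
            raw.append(core.format(R=sub))
    for core in templates_2:
        for s1 in _SUBSTITUENTS:
            for s2 in _SUBSTITUENTS:
                raw.append(core.format(R1=s1, R2=s2))
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - grammar is validated by tests
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen[canonical] = None
    return list(seen)


def generate_compounds(
    n: int, seed: int, decoy_fraction: float = 0.0
) -> List[Compound]:
    """Draw n unique compounds from the scaffold grammar, deterministic in seed.

    ``round(n * decoy_fraction)`` of them (exactly) lack the primary
    sulfonamide.  Raises when the grammar cannot supply enough molecules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= decoy_fraction <= 1:
        raise ValueError("decoy_fraction must be in [0, 1]")
    n_decoys = int(round(n * decoy_fraction))
    n_scaffold = n - n_decoys

    pool = _enumerate(_CORES_PLAIN, _CORES_1, _CORES_2)
    decoy_pool = _enumerate((), _DECOY_CORES_1, ())
    if n_scaffold > len(pool) or n_decoys > len(decoy_pool):
        raise ValueError(
            f"grammar capacity exceeded: {len(pool)} sulfonamides / "
            f"{len(decoy_pool)} decoys available, "
            f"{n_scaffold} / {n_decoys} requested"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    chosen = [pool[i] for i in rng.permutation(len(pool))[:n_scaffold]]
    chosen_decoys = [decoy_pool[i] for i in rng.permutation(len(decoy_pool))[:n_decoys]]

    compounds = [
        Compound(f"SYN{i + 1:05d}", smi, False) for i, smi in enumerate(chosen)
    ]
    compounds += [
        Compound(f"SYN{len(chosen) + i + 1:05d}", smi, True)
        for i, smi in enumerate(chosen_decoys)
    ]
    return compounds


# --------------------------------------------------------------------------
# study configuration

#: Base sparse latent weights on true descriptors (shared across isoforms).
DEFAULT_LATENT_WEIGHTS: Dict[str, float] = {
    "MolLogP": 0.9,
    "TPSA": -0.6,
    "MolWt": 0.45,
    "NumHDonors": -0.4,
    "NumHAcceptors": -0.25,
    "NumRotatableBonds": 0.5,
    "RingCount": -0.3,
    "FractionCSP3": 0.35,
}

#: Weights of the selectivity score.  Selectivity must be a function of
#: structure (not an unlearnable random flag), so the selective
#: subpopulation is the top fraction of this second descriptor direction,
#: deliberately different from the potency direction above.
DEFAULT_SELECTIVITY_WEIGHTS: Dict[str, float] = {
    "TPSA": 0.8,
    "NumHAcceptors": 0.6,
    "RingCount": 0.5,
    "MolLogP": -0.4,
    "NumHDonors": 0.3,
}


@dataclass(frozen=True)
class IsoformParams:
    """Location/scale of an isoform's log10 activity (nM) and its coverage."""

    mu_log10: float
    sigma_log10: float
    coverage: float = 1.0


def default_isoform_params() -> Dict[str, IsoformParams]:
    # hCA II: most data, strong skew below 100 nM, a real inactive tail.
    # hCA IX / XII: fewer records; XII has the fewest inactives, so its
    # validation sets run dry at larger sampling sizes.
    return {
        "hCA_II": IsoformParams(mu_log10=1.3, sigma_log10=1.3, coverage=1.0),
        "hCA_IX": IsoformParams(mu_log10=1.6, sigma_log10=1.1, coverage=0.85),
        "hCA_XII": IsoformParams(mu_log10=1.4, sigma_log10=0.9, coverage=0.70),
    }


@dataclass
class SyntheticStudyConfig:
    """Parameters of a synthetic study.

    ``noise_sd_log10`` is the per-measurement noise on the latent log10
    activity and doubles as the class-separation dial: lower noise means the
    descriptors determine the activity rank more strictly.
    """

    n_compounds: int = 800
    decoy_fraction: float = 0.05
    replicate_fraction: float = 0.10
    replicate_noise_sd_fraction: float = 0.05
    conflicting_replicate_fraction: float = 0.03
    censored_fraction: float = 0.25
    censor_min_nM: float = 1000.0
    noise_sd_log10: float = 0.30
    selectivity_fraction: float = 0.15
    selectivity_shift_log10: float = 2.0
    latent_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_WEIGHTS)
    )
    selectivity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SELECTIVITY_WEIGHTS)
    )
    isoform_weight_jitter: float = 0.15
    isoform_params: Dict[str, IsoformParams] = field(
        default_factory=default_isoform_params
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "decoy_fraction", "replicate_fraction", "conflicting_replicate_fraction",
            "censored_fraction", "selectivity_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["isoform_params"] = {
            k: asdict(v) if not isinstance(v, dict) else v
            for k, v in self.isoform_params.items()
        }
        return d


# --------------------------------------------------------------------------
# activity generation

def _latent_activities(
    compounds: Sequence[Compound], config: SyntheticStudyConfig
) -> pd.DataFrame:
    """Noise-free latent log10 activity per compound x isoform."""
    names = sorted(set(config.latent_weights) | set(config.selectivity_weights))
    table = compute_descriptors(
        [(c.compound_id, c.smiles) for c in compounds], descriptor_set=names
    )
    Z = table.values.copy()
    mean = np.nanmean(Z, axis=0)
    sd = np.nanstd(Z, axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mean) / sd
    Z = np.nan_to_num(Z, nan=0.0)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    w0 = np.array([config.latent_weights.get(n, 0.0) for n in names], dtype=float)
    n_compounds = len(compounds)
    # selectivity is structure-driven: the top fraction of a second
    # descriptor direction, so models can genuinely learn it
    w_sel = np.array(
        [config.selectivity_weights.get(n, 0.0) for n in names], dtype=float
    )
    sel_score = Z @ w_sel
    sel_spread = sel_score.std() or 1.0
    sel_score = (sel_score - sel_score.mean()) / sel_spread
    n_selective = int(round(config.selectivity_fraction * n_compounds))
    selective = np.zeros(n_compounds, dtype=bool)
    if n_selective:
        order = np.argsort(-sel_score, kind="stable")
        selective[order[:n_selective]] = True
        cutoff = sel_score[order[n_selective - 1]]
    else:
        cutoff = np.inf
    # graded shift: clearly selective structures get the full isoform shift,
    # borderline ones a partial shift (selectivity is graded in reality)
    shift_factor = 1.0 / (1.0 + np.exp(-(sel_score - cutoff) / 0.25))

    out = pd.DataFrame({
        "compound_id": [c.compound_id for c in compounds],
        "smiles": [c.smiles for c in compounds],
        "is_decoy": [c.is_decoy for c in compounds],
        "is_selective": selective,
        "selectivity_shift_factor": shift_factor,
    })
    for isoform in ISOFORMS:
        params = config.isoform_params[isoform]
        jitter = rng.normal(0.0, config.isoform_weight_jitter, size=len(w0))
        w = w0 * (1.0 + jitter)
        raw = Z @ w
        spread = raw.std() or 1.0
        s = (raw - raw.mean()) / spread
        latent = params.mu_log10 + params.sigma_log10 * s
        if isoform == "hCA_II":
            latent = latent + shift_factor * config.selectivity_shift_log10
        else:
            latent = latent - shift_factor * (config.selectivity_shift_log10 / 4.0)
        out[f"latent_log10_{isoform}"] = latent
        out[f"true_nM_{isoform}"] = 10.0 ** latent
        out[f"true_label_{isoform}"] = [
            fixed_label(v) for v in out[f"true_nM_{isoform}"]
        ]
    for pair in PAIRS:
        other = "hCA_IX" if pair == "II_vs_IX" else "hCA_XII"
        classes: List[Optional[str]] = []
        for l_II, l_other in zip(
            out["true_label_hCA_II"], out[f"true_label_{other}"]
        ):
            if "intermediate" in (l_II, l_other):
                classes.append(None)
            else:
                classes.append(combine_labels(l_II, l_other, pair))
        out[f"true_class_{pair}"] = classes
    return out


_TARGET_OF = {v: k for k, v in DEFAULT_TARGET_MAP.items()}


def generate_activities(
    compounds: Sequence[Compound], config: SyntheticStudyConfig
) -> Tuple[List[ActivityRecord], pd.DataFrame]:
    """Activity records (with replicates and censoring) plus the truth table."""
    truth = _latent_activities(compounds, config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))

    p_conflict = config.conflicting_replicate_fraction
    p_clean = max(config.replicate_fraction - p_conflict, 0.0)

    records: List[ActivityRecord] = []
    for row in truth.itertuples(index=False):
        for isoform in ISOFORMS:
            params = config.isoform_params[isoform]
            if rng.random() >= params.coverage:
                continue
            latent = getattr(row, f"latent_log10_{isoform}")
            base = 10.0 ** (latent + rng.normal(0.0, config.noise_sd_log10))
            u = rng.random()
            if u < p_conflict / 2:         # small conflicting group: discarded
                n_rep = int(rng.integers(2, 4))
                values = [base] + [
                    base * rng.uniform(5.0, 20.0) for _ in range(n_rep - 1)
                ]
            elif u < p_conflict:           # large conflicting group: mode rule
                n_wild = int(rng.integers(2, 4))
                values = [base] * 4 + [
                    base * rng.uniform(5.0, 50.0) for _ in range(n_wild)
                ]
            elif u < p_conflict + p_clean:  # consistent replicates: mean kept
                n_rep = int(rng.integers(2, 5))
                values = [
                    max(base * (1.0 + rng.normal(0.0, config.replicate_noise_sd_fraction)),
                        1e-4)
                    for _ in range(n_rep)
                ]
            else:
                values = [base]
            censored = (
                base > config.censor_min_nM
                and rng.random() < config.censored_fraction
            )
            for v in values:
                records.append(ActivityRecord(
                    compound_id=row.compound_id,
                    smiles=row.smiles,
                    target_id=_TARGET_OF[isoform],
                    endpoint_type="Ki" if rng.random() < 0.5 else "IC50",
                    relation=">" if censored else "=",
                    value=float(v),
                    units="nM",
                ))
    return records, truth


# --------------------------------------------------------------------------
# full study

@dataclass
class SyntheticStudy:
    """A generated study: raw export-shaped records plus ground truth."""

    config: SyntheticStudyConfig
    compounds: List[Compound]
    records: List[ActivityRecord]
    truth: pd.DataFrame

    @property
    def export_frame(self) -> pd.DataFrame:
        """Records in the flat ChEMBL export dialect read by curation."""
        return pd.DataFrame([{
            DEFAULT_COLUMNS["compound_id"]: r.compound_id,
            DEFAULT_COLUMNS["smiles"]: r.smiles,
            DEFAULT_COLUMNS["endpoint_type"]: r.endpoint_type,
            DEFAULT_COLUMNS["relation"]: r.relation,
            DEFAULT_COLUMNS["value"]: r.value,
            DEFAULT_COLUMNS["units"]: r.units,
            DEFAULT_COLUMNS["target_id"]: r.target_id,
        } for r in self.records])

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        """Write export.csv, truth.csv and the config echo; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "export": outdir / "export.csv",
            "truth": outdir / "truth.csv",
            "config": outdir / "config.json",
        }
        self.export_frame.to_csv(paths["export"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        paths["config"].write_text(json.dumps(self.config.to_dict(), indent=2))
        return paths


def generate_study(config: Optional[SyntheticStudyConfig] = None) -> SyntheticStudy:
    """Generate a full synthetic study from its config (seed-reproducible)."""
    if config is None:
        config = SyntheticStudyConfig()
    compounds = generate_compounds(
        config.n_compounds, seed=config.seed, decoy_fraction=config.decoy_fraction
    )
    records, truth = generate_activities(compounds, config)
    return SyntheticStudy(
        config=config, compounds=compounds, records=records, truth=truth
    )
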