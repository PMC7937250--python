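"""The synthetic study generator: determinism, constructed structure,
distribution emulation and truth-linked learnability."""

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats as sps

from casel import curation, descriptors, learning, sampling
from casel.curation import PRIMARY_SULFONAMIDE_SMARTS, filter_records, merge_replicates
from casel.synth import (
    SyntheticStudyConfig,
    generate_compounds,
    generate_study,
)

_ZBG = Chem.MolFromSmarts(PRIMARY_SULFONAMIDE_SMARTS)


class TestGenerateCompounds:
    def test_deterministic_and_unique(self):
        a = generate_compounds(100, seed=5, decoy_fraction=0.2)
        b = generate_compounds(100, seed=5, decoy_fraction=0.2)
        assert a == b
        assert len({c.smiles for c in a}) == 100

    def test_decoy_count_exact_and_warhead_consistent(self):
        compounds = generate_compounds(100, seed=1, decoy_fraction=0.2)
        decoys = [c for c in compounds if c.is_decoy]
        assert len(decoys) == 20
        for c in compounds:
            mol = Chem.MolFromSmiles(c.smiles)
            assert mol is not None
            assert mol.HasSubstructMatch(_ZBG) != c.is_decoy

    def test_single_compound_is_primary_sulfonamide(self):
        (c,) = generate_compounds(1, seed=0)
        assert Chem.MolFromSmiles(c.smiles).HasSubstructMatch(_ZBG)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_compounds(10_000, seed=0)


class TestGenerateStudy:
    def test_reproducible_from_seed(self, small_study):
        again = generate_study(SyntheticStudyConfig(n_compounds=300, seed=11))
        assert again.export_frame.equals(small_study.export_frame)
        assert again.truth.equals(small_study.truth)

    def test_replicate_fraction_matches_config(self, small_study):
        groups = {}
        for r in small_study.records:
            groups.setdefault((r.compound_id, r.target_id), []).append(r)
        frac = np.mean([len(g) > 1 for g in groups.values()])
        # binomial tolerance around the configured 10%
        assert abs(frac - small_study.config.replicate_fraction) < 0.04

    def test_conflicting_groups_trigger_curation_rules(self, small_study):
        kept, discarded = merge_replicates(filter_records(small_study.records))
        assert discarded, "small conflicting groups should be constructed"
        by_key = {}
        for r in filter_records(small_study.records):
            key = (r.compound_id, curation.DEFAULT_TARGET_MAP[r.target_id])
            by_key.setdefault(key, []).append(r.value)
        for key in discarded:
            values = np.array(by_key[key])
            assert len(values) <= 5
            assert values.std() >= 0.2 * values.mean()
        assert any(a.merge_rule == "mode_replaced" and a.n_records > 5
                   for a in kept)

    def test_censored_records_live_in_inactive_tail(self, small_study):
        censored = [r for r in small_study.records if r.relation == ">"]
        assert censored
        for r in censored:
            assert r.value > small_study.config.censor_min_nM / 25  # base in tail

    def test_selective_subpopulation_size_exact(self, small_study):
        truth = small_study.truth
        expected = round(small_study.config.selectivity_fraction * len(truth))
        assert int(truth.is_selective.sum()) == expected

    def test_truth_classes_follow_latent_labels(self, small_study):
        truth = small_study.truth
        sel = truth[truth.is_selective]
        # the shifted subpopulation is mostly weak on hCA II, potent on hCA IX
        assert (sel.true_nM_hCA_II > sel.true_nM_hCA_IX).mean() > 0.95

    def test_zero_noise_preserves_latent_rank_order(self):
        config = SyntheticStudyConfig(
            n_compounds=60, seed=3, noise_sd_log10=0.0,
            replicate_fraction=0.0, conflicting_replicate_fraction=0.0,
            censored_fraction=0.0, decoy_fraction=0.0,
        )
        study = generate_study(config)
        values = {r.compound_id: r.value for r in study.records
                  if r.target_id == "CHEMBL205"}
        truth = study.truth.set_index("compound_id")
        measured = [values[c] for c in truth.index if c in values]
        latent = [truth.true_nM_hCA_II[c] for c in truth.index if c in values]
        assert np.argsort(measured).tolist() == np.argsort(latent).tolist()


def test_activity_distribution_matches_configured_model():
    """The unshifted bulk of generated log-activities follows the configured
    per-isoform normal (location mu, scale sqrt(sigma^2 + noise^2)) within a
    loose KS bound — loose because the latent scores are descriptor-driven,
    not exactly Gaussian.  Selectivity-shifted compounds sit above the bulk
    on hCA II by the configured shift."""
    config = SyntheticStudyConfig(n_compounds=2000, seed=17, decoy_fraction=0.0)
    study = generate_study(config)
    truth = study.truth.set_index("compound_id")
    for isoform, target in [("hCA_II", "CHEMBL205"), ("hCA_IX", "CHEMBL3594")]:
        values = {}
        for r in study.records:
            if r.target_id == target:
                values.setdefault(r.compound_id, []).append(r.value)
        ids = list(values)
        logs = np.log10([np.mean(values[c]) for c in ids])
        shift = (config.selectivity_shift_log10 if isoform == "hCA_II"
                 else -config.selectivity_shift_log10 / 4)
        unshifted = logs - truth.selectivity_shift_factor[ids].to_numpy() * shift
        p = config.isoform_params[isoform]
        sd = np.hypot(p.sigma_log10, config.noise_sd_log10)
        D, _ = sps.kstest(unshifted, "norm", args=(p.mu_log10, sd))
        assert D < 0.06, f"{isoform}: KS distance {D:.3f}"
    # selective compounds: weak on hCA II relative to their own hCA IX
    # activity, by at least half the configured shift on average
    shifted = truth[truth.is_selective]
    contrast = (np.log10(shifted.true_nM_hCA_II)
                - np.log10(shifted.true_nM_hCA_IX)).mean()
    assert contrast > 0.5 * config.selectivity_shift_log10


def test_learnability_increases_with_class_separation():
    """Cross-validated MCC rises monotonically as measurement noise drops."""
    mccs = []
    for noise in (1.2, 0.45, 0.05):
        config = SyntheticStudyConfig(
            n_compounds=220, seed=29, noise_sd_log10=noise,
            decoy_fraction=0.0, replicate_fraction=0.0,
            conflicting_replicate_fraction=0.0, censored_fraction=0.0,
        )
        study = generate_study(config)
        frame = curation.activities_frame(merge_replicates(
            filter_records(study.records))[0])
        sub = frame[frame.isoform == "hCA_II"]
        acts = dict(zip(sub.compound_id, sub.activity_nM))
        dataset, _ = sampling.flexible_sample(acts, 50, "hCA_II")
        table = descriptors.drop_failed_compounds(descriptors.compute_descriptors(
            [(c, dict(zip(sub.compound_id, sub.smiles))[c])
             for c in dataset.compound_ids]
        ))
        X = table.feature_matrix(table.compound_ids)
        y = np.array([l for c, l in zip(dataset.compound_ids, dataset.labels)
                      if c in set(table.compound_ids)])
        cv = learning.cross_validate(X, y, "ET", k=5, seed=13)
        mccs.append(cv["mcc_mean"])
    assert mccs[0] < mccs[1] < mccs[2], mccs
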