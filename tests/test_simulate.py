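"""Cohort generator: count model, protocol effects, assignment tables."""

import numpy as np
import pandas as pd
import pytest

import deconvbench as db
from deconvbench.errors import ConfigurationError, DegenerateCompositionError
from deconvbench.simulate import _build_archetypes


def _block_fraction(bulk, blocks, name):
    return bulk.counts[blocks[name]].sum() / bulk.counts.sum()


class TestGenerateReference:
    def test_deterministic_given_seed(self, small_config):
        a = db.generate_reference(small_config, seed=3)
        b = db.generate_reference(small_config, seed=3)
        assert (a.X != b.X).nnz == 0
        pd.testing.assert_frame_equal(a.obs, b.obs)

    def test_library_size_equals_row_sum(self, small_ref):
        rows = np.asarray(small_ref.X.sum(axis=1)).ravel()
        assert np.array_equal(rows, small_ref.obs["library_size"].to_numpy())

    def test_single_type_zero_dispersion_recovers_archetype(self):
        cfg = db.CohortConfig(
            n_tumors=1, cells_per_tumor=500, n_genes=400,
            cell_types=("epithelial",), fragile_types=frozenset(),
            mean_composition={"epithelial": 1.0},
            patient_effect_sd=0.0, dispersion=0.0, rng_seed=1,
        )
        ref = db.generate_reference(cfg, seed=1)
        arch = _build_archetypes(cfg)[0]
        q = arch / arch.sum()
        pooled = np.asarray(ref.X.sum(axis=0)).ravel().astype(float)
        pooled /= pooled.sum()
        big = q > 1e-3
        assert np.max(np.abs(pooled[big] - q[big]) / q[big]) < 0.1

    def test_mrna_scale_doubles_library_size(self):
        cfg = db.CohortConfig(
            n_tumors=1, cells_per_tumor=2000, n_genes=300,
            cell_types=("epithelial", "T"), fragile_types=frozenset(),
            mean_composition={"epithelial": 0.5, "T": 0.5},
            mrna_scale={"epithelial": 2.0, "T": 1.0}, rng_seed=2,
        )
        ref = db.generate_reference(cfg, seed=2)
        lib = ref.obs.groupby("cell_type", observed=True)["library_size"].mean()
        assert lib["epithelial"] / lib["T"] == pytest.approx(2.0, rel=0.08)

    def test_default_cohort_scale(self, default_ref):
        assert default_ref.obs["sample_id"].nunique() == 8
        assert default_ref.obs["cell_type"].nunique() == 10
        present = default_ref.obs.groupby("sample_id", observed=True)["cell_type"].nunique()
        assert (present == 10).all()  # every type present in every tumor

    def test_invalid_composition_rejected(self):
        with pytest.raises(ConfigurationError):
            db.CohortConfig(mean_composition={"epithelial": 0.7})  # sums to 0.7

    def test_fragile_flag_restricted(self):
        with pytest.raises(ConfigurationError):
            db.CohortConfig(fragile_types=frozenset({"T"}))


class TestGenerateBulk:
    def test_counts_sum_to_depth_and_truth_sums_to_one(self, small_ref):
        b = db.generate_bulk(small_ref, "tumor01",
                             db.protocol_presets()["rRNA_chunk"],
                             depth=100_000, seed=4)
        assert b.counts.sum() == 100_000
        assert b.true_composition.sum() == pytest.approx(1.0, abs=1e-9)
        assert (b.counts >= 0).all()

    def test_identity_protocol_matches_unmodified_mixture(self, small_ref):
        """Neutral protocol: expectation equals the raw RNA-share mixture (oracle)."""
        neutral = db.ProtocolEffects(
            dissociated=False, enrichment="rRNA_depletion",
            histone_polyA_retention=1.0, mito_depletion_rRNA=1.0,
        )
        b = db.generate_bulk(small_ref, "tumor01", neutral, depth=2_000_000, seed=4)
        # independent oracle: aggregate counts of the tumor's cells
        mask = np.asarray(small_ref.obs["sample_id"] == "tumor01")
        agg = np.asarray(small_ref.X[mask].sum(axis=0)).ravel().astype(float)
        expected = agg / agg.sum()
        observed = b.counts.to_numpy() / b.counts.sum()
        big = expected > 1e-3
        assert np.max(np.abs(observed[big] - expected[big]) / expected[big]) < 0.1
        # truth equals the observed RNA shares per type
        ct = small_ref.obs.loc[mask, "cell_type"].astype(str)
        lib = small_ref.obs.loc[mask, "library_size"]
        shares = lib.groupby(ct).sum() / lib.sum()
        for cell_type, share in shares.items():
            assert b.true_composition[cell_type] == pytest.approx(share, abs=1e-9)

    def test_dissociation_strictly_lowers_hemoglobin(self, small_ref):
        presets = db.protocol_presets()
        chunk = db.generate_bulk(small_ref, "tumor01", presets["rRNA_chunk"],
                                 depth=1_000_000, seed=5)
        diss = db.generate_bulk(small_ref, "tumor01", presets["rRNA_dissociated"],
                                depth=1_000_000, seed=5)
        hb = small_ref.uns["marker_blocks"]["hemoglobin"]
        assert diss.counts[hb].sum() < chunk.counts[hb].sum()

    def test_enrichment_fold_change_windows(self, small_ref):
        presets = db.protocol_presets()
        blocks = small_ref.uns["marker_blocks"]
        rrna = db.generate_bulk(small_ref, "tumor02", presets["rRNA_dissociated"],
                                depth=5_000_000, seed=6)
        polya = db.generate_bulk(small_ref, "tumor02", presets["polyA_dissociated"],
                                 depth=5_000_000, seed=6)
        hist_ratio = _block_fraction(rrna, blocks, "histone") / _block_fraction(polya, blocks, "histone")
        mito_ratio = _block_fraction(polya, blocks, "mitochondrial") / _block_fraction(rrna, blocks, "mitochondrial")
        assert hist_ratio >= 1.7
        assert mito_ratio >= 10.0

    def test_stress_induction_monotone(self, small_ref):
        """Higher stress induction raises the stress-block share (10 replicates)."""
        blocks = small_ref.uns["marker_blocks"]
        fracs = {}
        for s in (1.0, 5.0):
            proto = db.ProtocolEffects(dissociated=True, enrichment="rRNA_depletion",
                                       stress_induction=s)
            vals = [
                _block_fraction(
                    db.generate_bulk(small_ref, "tumor01", proto, depth=200_000, seed=k),
                    blocks, "stress")
                for k in range(10)
            ]
            fracs[s] = np.mean(vals)
        assert fracs[5.0] > fracs[1.0]

    def test_erythrocyte_retention_monotone(self, small_ref):
        blocks = small_ref.uns["marker_blocks"]
        means = {}
        for r in (0.8, 0.2):
            proto = db.ProtocolEffects(dissociated=True, enrichment="rRNA_depletion",
                                       erythrocyte_retention=r)
            vals = [
                db.generate_bulk(small_ref, "tumor01", proto, depth=200_000,
                                 seed=k).counts[list(blocks["hemoglobin"])].sum()
                for k in range(10)
            ]
            means[r] = np.mean(vals)
        assert means[0.2] < means[0.8]

    def test_degenerate_composition_raises(self, two_type_adata):
        proto = db.ProtocolEffects(dissociated=True, enrichment="rRNA_depletion")
        # a dataset of only fragile types loses everything on dissociation
        only_fragile = two_type_adata.copy()
        only_fragile.obs["cell_type"] = pd.Categorical(
            ["erythrocyte"] * 40 + ["adipocyte"] * 40)
        with pytest.raises(DegenerateCompositionError):
            db.generate_bulk(only_fragile, "s1", proto, depth=1000, seed=0)

    def test_unknown_tumor_raises(self, small_ref):
        with pytest.raises(ConfigurationError):
            db.generate_bulk(small_ref, "nope", db.protocol_presets()["rRNA_chunk"],
                             depth=1000, seed=0)


class TestAssignmentTables:
    def test_perfect_adhesion_concentrates_posterior(self, small_ref):
        pairs = db.generate_assignment_tables(
            small_ref, [["tumor01", "tumor02"]], hash_adhesion=1.0,
            doublet_rate=0.0, seed=9)
        hash_t, _ = pairs[0]
        p_true = np.array([
            hash_t.posteriors.loc[bc, s]
            for bc, s in hash_t.true_sample.items()
        ])
        assert (p_true >= 0.99).all()

    def test_rows_are_posteriors(self, small_ref):
        pairs = db.generate_assignment_tables(small_ref, [["tumor01", "tumor02"]],
                                              doublet_rate=0.05, seed=9)
        for table in pairs[0]:
            P = table.posteriors.to_numpy()
            assert (P >= 0).all()
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_low_adhesion_sample_has_most_unassigned(self, small_ref):
        pairs = db.generate_assignment_tables(
            small_ref, [["tumor01", "tumor02"]],
            hash_adhesion={"tumor01": 0.2, "tumor02": 0.9},
            doublet_rate=0.0, seed=10)
        hash_t, _ = pairs[0]
        prev_unassigned = None
        for thr in (0.90, 0.85, 0.80):
            labels = db.call_assignments(hash_t, thr).labels
            unassigned_by_true = (
                (labels == "unassigned").groupby(hash_t.true_sample).mean())
            assert unassigned_by_true["tumor01"] > unassigned_by_true["tumor02"]
            total_unassigned = int((labels == "unassigned").sum())
            if prev_unassigned is not None:
                assert total_unassigned <= prev_unassigned
            prev_unassigned = total_unassigned

    def test_two_pools_emit_two_pairs(self, default_ref):
        tumors = [str(t) for t in default_ref.obs["sample_id"].cat.categories]
        pairs = db.generate_assignment_tables(
            default_ref, [tumors[:4], tumors[4:]], seed=1)
        assert len(pairs) == 2
        for hash_t, gen_t in pairs:
            assert hash_t.modality == "hash" and gen_t.modality == "genetic"
            assert len(hash_t.samples) == 4

    def test_doublets_carry_multiplet_mass(self, small_ref):
        pairs = db.generate_assignment_tables(small_ref, [["tumor01", "tumor02"]],
                                              doublet_rate=0.1, seed=12)
        hash_t, gen_t = pairs[0]
        doublets = hash_t.true_sample == "multiplet"
        assert doublets.sum() == round(0.1 * len(hash_t.true_sample))
        for table in (hash_t, gen_t):
            mult = table.posteriors.loc[doublets.to_numpy(), "multiplet"]
            assert (mult > 0.5).mean() > 0.9

    def test_non_partition_rejected(self, small_ref):
        with pytest.raises(ConfigurationError):
            db.generate_assignment_tables(small_ref, [["tumor01"]], seed=0)
        with pytest.raises(ConfigurationError):
            db.generate_assignment_tables(
                small_ref, [["tumor01", "tumor02"], ["tumor02"]], seed=0)

    def test_deterministic(self, small_ref):
        a = db.generate_assignment_tables(small_ref, [["tumor01", "tumor02"]], seed=3)
        b = db.generate_assignment_tables(small_ref, [["tumor01", "tumor02"]], seed=3)
        pd.testing.assert_frame_equal(a[0][0].posteriors, b[0][0].posteriors)
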