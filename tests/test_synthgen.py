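"""The synthetic-world generator: scaffold/bit-flip chemistry, calibrated
signature spaces, activity sampling, presets and determinism."""

import filecmp

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu

from gesbench import synthgen
from gesbench.synthgen import (
    ScenarioConfig,
    TargetSpec,
    expected_within_scaffold_dice,
    generate_activity,
    generate_compounds,
    generate_signatures,
    make_scenario,
    make_world,
)


def config(**kw):
    base = dict(
        n_compounds=200,
        cell_lines=("A549",),
        n_scaffolds=4,
        bit_length=256,
        targets=(TargetSpec(target_id="T1", active_fraction=0.2),),
        seed=5,
    )
    base.update(kw)
    return ScenarioConfig(**base)


def actives_fp_matrix(world, target):
    ids = set(world.truth["targets"][target]["actives"])
    return np.array(
        [c.fingerprint for c in world.compounds if c.compound_id in ids]
    ).astype(bool)


def actives_z_matrix(world, target, cell):
    ids = set(world.truth["targets"][target]["actives"])
    sig = {
        (r.compound_id, r.cell_line): r.z
        for r in world.signatures
        if r.cell_line == cell
    }
    return np.array([sig[(i, cell)] for i in sorted(ids)])


class TestCompounds:
    def test_zero_flip_rate_within_scaffold_identity(self):
        cfg = config(within_scaffold_flip_rate=0.0)
        compounds, scaffold_of = generate_compounds(cfg)
        fps = np.array([c.fingerprint for c in compounds])
        for s in range(cfg.n_scaffolds):
            members = fps[scaffold_of == s]
            assert (members == members[0]).all()

    def test_disjoint_scaffolds_cross_distance_one(self):
        # no shared core bits, no flips -> different scaffolds share nothing
        # (up to random base-pattern collisions, excluded here by seed search
        # over the generated bases)
        cfg = config(n_core_bits=0, within_scaffold_flip_rate=0.0, n_scaffolds=2,
                     bit_length=2048, fp_density=0.01)
        compounds, scaffold_of = generate_compounds(cfg)
        fps = np.array([c.fingerprint for c in compounds], dtype=bool)
        a = fps[scaffold_of == 0][0]
        b = fps[scaffold_of == 1][0]
        if np.any(a & b):  # random overlap: regenerate is not allowed, assert softly
            pytest.skip("random base patterns overlapped")
        from gesbench.chemdesc import dice_distance

        assert dice_distance(a, b) == 1.0

    def test_within_scaffold_dice_matches_closed_form(self):
        cfg = config(
            n_compounds=400,
            n_scaffolds=4,
            bit_length=1024,
            fp_density=0.05,
            within_scaffold_flip_rate=0.02,
        )
        compounds, scaffold_of = generate_compounds(cfg)
        fps = np.array([c.fingerprint for c in compounds], dtype=bool)
        within, cross = [], []
        for s in range(cfg.n_scaffolds):
            within.append(pdist(fps[scaffold_of == s], "dice").mean())
        rng = np.random.default_rng(0)
        for _ in range(1000):
            i, j = rng.choice(len(fps), 2, replace=False)
            if scaffold_of[i] != scaffold_of[j]:
                from gesbench.chemdesc import dice_distance

                cross.append(dice_distance(fps[i], fps[j]))
        assert np.mean(within) < np.mean(cross)
        expected = expected_within_scaffold_dice(
            int(round(cfg.fp_density * cfg.bit_length)),
            cfg.bit_length,
            cfg.within_scaffold_flip_rate,
        )
        assert np.mean(within) == pytest.approx(expected, abs=0.03)

    def test_more_scaffolds_than_compounds_raises(self):
        with pytest.raises(ValueError, match="more scaffolds than compounds"):
            generate_compounds(config(n_compounds=3, n_scaffolds=4))


class TestActivity:
    def test_dense_when_fully_observed(self):
        cfg = config(observed_fraction=1.0)
        compounds, scaffold_of = generate_compounds(cfg)
        activity, _ = generate_activity(cfg, compounds, scaffold_of)
        assert len(activity) == cfg.n_compounds  # one target, every pair labeled

    def test_active_count_in_binomial_interval(self):
        cfg = config(
            n_compounds=2000,
            n_scaffolds=20,
            targets=(TargetSpec(target_id="T1", active_fraction=0.05),),
        )
        compounds, scaffold_of = generate_compounds(cfg)
        activity, _ = generate_activity(cfg, compounds, scaffold_of)
        assert 80 <= activity.n_actives("T1") <= 120

    def test_chem_coherent_actives_share_host_scaffolds(self):
        cfg = config(
            n_compounds=1000,
            n_scaffolds=10,
            targets=(
                TargetSpec(target_id="T1", active_fraction=0.1, chem_coherent=True),
            ),
        )
        compounds, scaffold_of = generate_compounds(cfg)
        activity, truth = generate_activity(cfg, compounds, scaffold_of)
        hosts = set(truth["T1"]["host_scaffolds"])
        idx = {c.compound_id: i for i, c in enumerate(compounds)}
        in_host = [scaffold_of[idx[a]] in hosts for a in truth["T1"]["actives"]]
        assert np.mean(in_host) >= 0.9


class TestSignatures:
    def test_noiseless_world_gives_identical_active_signatures(self):
        cfg = config(
            noise_sd=0.0,
            targets=(
                TargetSpec(
                    target_id="T1",
                    active_fraction=0.2,
                    responsive_cell_lines=("A549",),
                ),
            ),
        )
        world = make_world(cfg)
        Z = actives_z_matrix(world, "T1", "A549")
        assert pdist(Z, "cosine").max() == pytest.approx(0.0, abs=1e-12)

    def test_tubb_like_calibration_band(self):
        world = make_scenario("tubb_like", 3, n_compounds=1200)
        for cell in world.config.cell_lines:
            Z = actives_z_matrix(world, "TUBBsim", cell)
            assert len(Z) >= 30
            assert 0.61 <= pdist(Z, "cosine").mean() <= 0.75

    def test_drd1_like_background_band(self):
        world = make_scenario("drd1_like", 3, n_compounds=1200)
        for cell in world.config.cell_lines:
            Z = actives_z_matrix(world, "DRD1sim", cell)
            assert pdist(Z, "cosine").mean() >= 0.85

    def test_calibration_tolerance_band(self, small_world):
        # realized mean cosine distance among actives within ±0.05 of target
        Z = actives_z_matrix(small_world, "T1", "A549")
        assert len(Z) >= 30
        target = small_world.config.targets[0].active_cosine_target
        assert pdist(Z, "cosine").mean() == pytest.approx(target, abs=0.05)

    def test_invalid_cosine_target_rejected(self):
        with pytest.raises(ValueError, match="active_cosine_target"):
            config(
                targets=(TargetSpec(target_id="T1", active_cosine_target=2.5),)
            ).validate()

    def test_nonresponsive_actives_indistinguishable_from_background(self):
        # two-sample location test at α=0.01 over 20 seeds: the actives'
        # internal pair distances come from the same process as background
        # internal pair distances, so rejections should stay at test level
        rejections = 0
        for s in range(20):
            cfg = config(
                n_compounds=150,
                n_genes=150,
                targets=(
                    TargetSpec(target_id="T1", active_fraction=0.2),
                ),  # no responsive cell lines
                seed=100 + s,
            )
            world = make_world(cfg)
            act = set(world.truth["targets"]["T1"]["actives"])
            Z = {r.compound_id: r.z for r in world.signatures}
            a = pdist(np.array([Z[i] for i in sorted(act)]), "cosine")
            bg_ids = sorted(set(Z) - act)[: len(act)]
            b = pdist(np.array([Z[i] for i in bg_ids]), "cosine")
            if mannwhitneyu(a, b).pvalue < 0.01:
                rejections += 1
        assert rejections <= 2  # non-rejection rate ≥ 0.9


class TestScenarios:
    def test_tubb_like_truth_lists_all_cell_lines_responsive(self):
        world = make_scenario("tubb_like", 1, n_compounds=300)
        spec = world.config.targets[0]
        assert set(spec.responsive_cell_lines) == set(world.config.cell_lines)

    def test_drd1_like_actives_chemically_diverse(self):
        world = make_scenario("drd1_like", 1, n_compounds=1200)
        assert pdist(actives_fp_matrix(world, "DRD1sim"), "dice").mean() > 0.75

    def test_mixed_spans_regimes(self):
        world = make_scenario("mixed", 1, n_compounds=200)
        specs = world.config.targets
        assert len(specs) >= 20
        assert any(t.responsive_cell_lines for t in specs)
        assert any(not t.responsive_cell_lines for t in specs)
        assert any(t.chem_coherent for t in specs)

    def test_same_seed_byte_identical_worlds(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        make_scenario("nr3c1_like", 1, n_compounds=200).write(a)
        make_scenario("nr3c1_like", 1, n_compounds=200).write(b)
        for name in ("compounds.tsv", "fingerprints.tsv", "signatures.tsv",
                     "sigmeta.tsv", "activity.tsv", "truth.json"):
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_scenario("nope", 1)

    def test_signatures_unique_per_compound_cell_condition(self, small_world):
        keys = [
            (r.compound_id, r.cell_line, r.dose, r.time) for r in small_world.signatures
        ]
        assert len(keys) == len(set(keys))
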