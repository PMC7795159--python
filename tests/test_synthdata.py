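"""Generator tests: determinism, planted effects, couplings, read mixtures."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tepomics import (
    DEFAULT_CLASS_PROBS,
    GeneratorConfig,
    SyntheticTruth,
    generate_expression,
    generate_gene_sets,
    generate_reads,
    generate_reference,
)
from tepomics.normfilter import cpm


SMALL = dict(n_mirna=20, n_mrna=60, n_intron=30, n_protein=30,
             lib_size_log_mean=np.log(2e4))


class TestGeneratorConfig:
    def test_defaults_valid(self):
        GeneratorConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_de": 1.5},
            {"nb_dispersion": -0.1},
            {"n_samples_per_group": 1},
            {"n_protein_samples_a": 0},
            {"n_intron": 500},
            {"n_regulators": 2},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_class_probs_must_sum_to_one(self):
        probs = {g: dict(v) for g, v in DEFAULT_CLASS_PROBS.items()}
        probs["A"]["canonical"] += 0.05
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(class_probs_by_group=probs)


class TestGenerateReference:
    def test_forced_length_and_flanks(self):
        ref = generate_reference(1, (21, 21), 8, seed=1)
        assert len(ref) == 1
        assert len(ref[0].mature_seq) == 21
        assert len(ref[0].flank5) == len(ref[0].flank3) == 8

    def test_deterministic_given_seed(self):
        assert generate_reference(5, (18, 24), 10, seed=1) == generate_reference(
            5, (18, 24), 10, seed=1
        )

    def test_repertoire_scale_unique_names(self):
        ref = generate_reference(344, (18, 24), 10, seed=7)
        assert len(ref) == 344
        assert len({r.name for r in ref}) == 344
        assert all(set(r.mature_seq) <= set("ACGU") for r in ref)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(3, (10, 21), 8)
        with pytest.raises(ValueError):
            generate_reference(3, (18, 21), 2)


class TestGenerateExpression:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(**SMALL, seed=3)
        m1, t1 = generate_expression(cfg)
        m2, t2 = generate_expression(cfg)
        for layer in m1:
            pd.testing.assert_frame_equal(m1[layer].counts, m2[layer].counts)
        assert t1 == t2

    def test_layer_shapes_and_protein_subset(self):
        cfg = GeneratorConfig(**SMALL, seed=0)
        mats, truth = generate_expression(cfg)
        assert mats["mirna"].counts.shape == (20, 22)
        assert mats["protein"].counts.shape[1] == 8 + 11
        assert set(mats["intron"].features) <= set(mats["mrna"].features)
        assert (mats["protein"].groups == "A").sum() == 8

    def test_truth_invariants(self):
        cfg = GeneratorConfig(**SMALL, seed=1)
        mats, truth = generate_expression(cfg)
        for layer, planted in truth.de_features.items():
            for f in planted:
                assert f in mats[layer].features.tolist()
        hub_regs = [m for m, ts in truth.target_map.items() if truth.hub_transcript in ts]
        assert len(hub_regs) >= 5
        assert truth.hub_transcript in mats["mrna"].features
        assert truth.hub_transcript in mats["intron"].features

    def test_no_de_when_frac_zero(self):
        cfg = GeneratorConfig(**SMALL, frac_de=0.0, seed=2)
        _, truth = generate_expression(cfg)
        assert all(len(v) == 0 for v in truth.de_features.values())

    def test_zero_beta_gives_uncorrelated_targets(self):
        cfg = GeneratorConfig(**SMALL, repression_beta=0.0, regulator_cor=0.0, seed=4)
        mats, truth = generate_expression(cfg)
        c_m = np.log2(cpm(mats["mirna"]) + 1)
        c_g = np.log2(cpm(mats["mrna"]) + 1)
        rs = []
        for reg, targets in truth.target_map.items():
            for t in targets:
                rs.append(np.corrcoef(c_m.loc[reg], c_g.loc[t])[0, 1])
        # pad with random pairs so the mean is over ~100 couplings
        rng = np.random.default_rng(0)
        while len(rs) < 100:
            m = rng.choice(c_m.index)
            g = rng.choice(c_g.index)
            rs.append(np.corrcoef(c_m.loc[m], c_g.loc[g])[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_planted_coupling_gives_negative_median_correlation(self):
        rs = []
        for seed in range(5):
            cfg = GeneratorConfig(**SMALL, seed=seed)
            mats, truth = generate_expression(cfg)
            c_m = np.log2(cpm(mats["mirna"]) + 1)
            c_g = np.log2(cpm(mats["mrna"]) + 1)
            for reg, targets in truth.target_map.items():
                for t in targets:
                    rs.append(np.corrcoef(c_m.loc[reg], c_g.loc[t])[0, 1])
        assert np.median(rs) < -0.3

    def test_protein_coupling_gives_positive_correlation(self):
        cfg = GeneratorConfig(**SMALL, seed=6)
        mats, truth = generate_expression(cfg)
        c_g = np.log2(cpm(mats["mrna"]) + 1)
        c_p = np.log2(cpm(mats["protein"]) + 1)
        shared = [s for s in c_p.columns if s in c_g.columns]
        rs = [
            np.corrcoef(c_g.loc[g, shared], c_p.loc[p, shared])[0, 1]
            for g, p in truth.protein_map.items()
        ]
        assert np.median(rs) > 0.3

    def test_planted_lfc_recovered_from_counts(self):
        """Mean |estimated log2FC| of planted mRNA features near the planted 2."""
        errs = []
        for seed in range(50):
            cfg = GeneratorConfig(**SMALL, seed=300 + seed)
            mats, truth = generate_expression(cfg)
            c = cpm(mats["mrna"])
            a = mats["mrna"].samples_in_group("A")
            b = mats["mrna"].samples_in_group("B")
            planted = {
                f: lfc for f, lfc in truth.de_features["mrna"].items()
                if f != truth.hub_transcript
                and all(f not in t for t in truth.target_map.values())
            }
            est = np.log2((c.loc[list(planted), a].mean(axis=1) + 0.5)
                          / (c.loc[list(planted), b].mean(axis=1) + 0.5))
            errs.append(np.abs(est).mean())
        assert abs(np.mean(errs) - 2.0) < 0.3

    def test_truth_round_trips_through_json(self, tmp_path):
        cfg = GeneratorConfig(**SMALL, seed=8)
        _, truth = generate_expression(cfg)
        truth.to_json(tmp_path / "truth.json")
        assert SyntheticTruth.from_json(tmp_path / "truth.json") == truth


class TestGenerateReads:
    def test_conservation_and_determinism(self, tiny_ref):
        reads1, labels1, groups = generate_reads(tiny_ref, reads_per_sample=200,
                                                 n_samples_per_group=2, seed=5)
        reads2, labels2, _ = generate_reads(tiny_ref, reads_per_sample=200,
                                            n_samples_per_group=2, seed=5)
        assert reads1 == reads2 and labels1 == labels2
        assert all(len(r) == 200 for r in reads1.values())
        assert set(groups.unique()) == {"A", "B"}

    def test_pure_canonical_mixture_emits_mature_sequences(self, tiny_ref):
        probs = {"A": {"canonical": 1.0}, "B": {"canonical": 1.0}}
        reads, labels, _ = generate_reads(tiny_ref, probs, reads_per_sample=100,
                                          n_samples_per_group=1, seed=1)
        mature = {r.mature_seq for r in tiny_ref}
        assert all(read in mature for read in reads["A01"])

    def test_pure_nta_t_mixture_appends_nontemplated_poly_u(self, tiny_ref):
        probs = {"A": {"nta#T": 1.0}, "B": {"canonical": 1.0}}
        reads, labels, _ = generate_reads(tiny_ref, probs, reads_per_sample=100,
                                          n_samples_per_group=1, seed=2)
        by_name = {r.name: r for r in tiny_ref}
        for read, (parent, cls) in zip(reads["A01"], labels["A01"]):
            assert cls == "nta#T"
            ref = by_name[parent]
            assert read.startswith(ref.mature_seq)
            tail = read[len(ref.mature_seq):]
            assert tail and set(tail) == {"U"}
            assert ref.flank3[0] != "U"

    def test_empirical_class_fractions_match_mixture(self):
        ref = generate_reference(40, (18, 24), 10, seed=9)
        reads, labels, _ = generate_reads(ref, reads_per_sample=10_000,
                                          n_samples_per_group=2, seed=10)
        for g in ("A", "B"):
            drawn = [cls for s in (f"{g}01", f"{g}02") for _, cls in labels[s]]
            total = len(drawn)
            for cls, p in DEFAULT_CLASS_PROBS[g].items():
                assert abs(drawn.count(cls) / total - p) < 0.01


class TestGeneSets:
    def test_sets_cover_planted_and_respect_sizes(self):
        universe = [f"g{i}" for i in range(100)]
        sets = generate_gene_sets(universe, n_sets=10, size_range=(5, 15), seed=1,
                                  planted={"PLANTED": universe[:7]})
        assert len(sets) == 11
        assert sets["PLANTED"] == sorted(universe[:7])
        for name, members in sets.items():
            if name != "PLANTED":
                assert 5 <= len(members) <= 15
                assert set(members) <= set(universe)
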