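"""Planted-structure recovery and determinism of the synthetic generators."""

import numpy as np
import pytest

from immunoconverge import (
    build_compound_exons,
    classify_deleterious,
    connectivity,
    build_network,
    deconfounded_pair,
    hematopoietic_fold,
    pairwise_overlap,
    tissue_profile,
)
from immunoconverge.synthetic_data import (
    BurdenRates,
    NetworkParams,
    SyntheticConfig,
    default_config,
    gen_catalog,
    gen_exome_and_variants,
    gen_expression,
    gen_genesets,
    gen_network,
    generate_all,
    load_scenario,
    HEMATOPOIETIC_CELLS,
)


def small_config(seed=0, **kw):
    base = default_config(seed)
    diseases = ("AS", "CD", "UC")
    cfg = SyntheticConfig(
        seed=seed,
        diseases=diseases,
        set_sizes={"AS": 10, "CD": 20, "UC": 15},
        membership_patterns=((frozenset({"AS", "CD"}), 3), (frozenset({"AS", "UC"}), 2)),
        network_params=NetworkParams(n_nodes=80, p_background=0.05, p_planted=0.25,
                                     planted_pairs=(("AS", "CD"), ("AS", "UC"))),
        planted_pathway=base.planted_pathway,
        **kw,
    )
    return cfg


class TestGenCatalog:
    def test_disjoint_design_gives_disjoint_sets(self):
        cfg = SyntheticConfig(seed=0, diseases=("A", "B"), set_sizes={"A": 5, "B": 7},
                              membership_patterns=())
        cat = gen_catalog(cfg)
        assert not cat.genes("A") & cat.genes("B")

    def test_infeasible_design_errors(self):
        cfg = SyntheticConfig(seed=0, diseases=("A", "B"), set_sizes={"A": 2, "B": 5},
                              membership_patterns=((frozenset({"A", "B"}), 3),))
        with pytest.raises(ValueError, match="infeasible"):
            gen_catalog(cfg)

    def test_pairwise_overlaps_recovered_exactly_for_random_designs(self, rng):
        diseases = tuple(f"D{i}" for i in range(5))
        for _ in range(25):
            patterns = []
            used = {d: 0 for d in diseases}
            for _ in range(int(rng.integers(1, 6))):
                k = int(rng.integers(2, 4))
                pat = frozenset(rng.choice(diseases, size=k, replace=False))
                count = int(rng.integers(1, 4))
                patterns.append((pat, count))
                for d in pat:
                    used[d] += count
            sizes = {d: used[d] + int(rng.integers(1, 10)) for d in diseases}
            cfg = SyntheticConfig(seed=1, diseases=diseases, set_sizes=sizes,
                                  membership_patterns=tuple(patterns))
            cat = gen_catalog(cfg)
            for a in diseases:
                got = pairwise_overlap(cat, a)
                for b in diseases:
                    if a == b:
                        continue
                    expected = sum(c for pat, c in patterns if {a, b} <= pat)
                    assert got[b] == expected
            for d in diseases:
                assert len(cat.genes(d)) == sizes[d]

    def test_default_scenario_matches_shipped_yaml(self, default_catalog):
        from pathlib import Path
        scenario = Path(__file__).resolve().parents[1] / "scenarios" / "default.yaml"
        cfg = load_scenario(scenario, seed=0)
        assert dict(gen_catalog(cfg).entries) == dict(default_catalog.entries)


class TestGenExome:
    def test_zero_constrained_rate_gives_no_deleterious_variants(self):
        cfg = small_config(burden_rates=BurdenRates(lambda_constrained=0.0))
        genes = [f"G{i}" for i in range(20)]
        labels = {g: "constrained" for g in genes}
        _, variants = gen_exome_and_variants(cfg, genes, labels)
        assert classify_deleterious(variants, 0.01) == []

    def test_deleterious_count_tracks_poisson_mean(self):
        lam = 0.02
        cfg = small_config(seed=4, burden_rates=BurdenRates(lambda_tolerated=lam))
        genes = [f"G{i}" for i in range(500)]
        labels = {g: "tolerated" for g in genes}
        intervals, variants = gen_exome_and_variants(cfg, genes, labels)
        total_len = sum(m.total_length for m in build_compound_exons(intervals).values())
        n_del = sum(v.consequence != "synonymous" for v in variants)
        expected = lam * total_len
        assert abs(n_del - expected) <= 3 * np.sqrt(expected)

    def test_doubling_rate_doubles_expected_counts(self):
        genes = [f"G{i}" for i in range(400)]
        labels = {g: "tolerated" for g in genes}
        counts = []
        for lam in (0.01, 0.02):
            cfg = small_config(seed=9, burden_rates=BurdenRates(lambda_tolerated=lam))
            _, variants = gen_exome_and_variants(cfg, genes, labels)
            counts.append(sum(v.consequence != "synonymous" for v in variants))
        assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.15)

    def test_unknown_group_label_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="group"):
            gen_exome_and_variants(cfg, ["G1"], {"G1": "mystery"})


class TestGenExpression:
    def test_unit_boost_leaves_risk_genes_at_baseline(self):
        from immunoconverge import ks_compare
        cfg = small_config(seed=2)
        cfg = SyntheticConfig(**{**cfg.__dict__,
                                 "expression_boost": cfg.expression_boost.__class__(
                                     tissues=HEMATOPOIETIC_CELLS, factor=1.0)})
        genes = [f"G{i}" for i in range(300)]
        _, spectra = gen_expression(cfg, genes, boosted_genes=genes[:50])
        risk = spectra.values.loc[genes[:50]].to_numpy().ravel()
        rest = spectra.values.loc[genes[50:]].to_numpy().ravel()
        assert ks_compare(risk, rest).p_value > 0.01

    def test_boost_factor_three_yields_twofold_hematopoietic_ratio(self):
        cfg = default_config(11)
        genes = [f"G{i}" for i in range(400)]
        _, spectra = gen_expression(cfg, genes, boosted_genes=genes[:30])
        summary = tissue_profile(spectra, genes[:30])
        assert hematopoietic_fold(summary, HEMATOPOIETIC_CELLS) >= 2.0

    def test_zero_variance_baseline_gives_exact_mean_fold(self):
        cfg = small_config(log_sigma=0.0)
        genes = [f"G{i}" for i in range(50)]
        _, spectra = gen_expression(cfg, genes, boosted_genes=genes)
        summary = tissue_profile(spectra, genes)
        hema_mean = np.mean([summary.per_tissue_mean[t] for t in HEMATOPOIETIC_CELLS])
        other = [t for t in summary.per_tissue_mean if t not in HEMATOPOIETIC_CELLS]
        other_mean = np.mean([summary.per_tissue_mean[t] for t in other])
        assert hema_mean / other_mean == pytest.approx(cfg.expression_boost.factor)

    def test_fpkm_annotation_covers_all_transcripts(self):
        cfg = small_config()
        fpkm, _ = gen_expression(cfg, [f"G{i}" for i in range(30)])
        assert set(fpkm.row_to_gene) == set(fpkm.row_ids)


class TestGenGenesets:
    def test_planted_set_holds_query_fraction(self, default_catalog):
        cfg = default_config(3)
        db, _ = gen_genesets(cfg, default_catalog.all_genes(),
                             planted_from=default_catalog.genes("AS"))
        planted = db.genes_of("SET_PLANTED")
        overlap = len(planted & default_catalog.genes("AS"))
        assert overlap == int(0.5 * len(default_catalog.genes("AS")))
        assert len(planted) == cfg.planted_pathway.size

    def test_all_set_sizes_within_bounds(self, default_catalog):
        cfg = default_config(3)
        db, _ = gen_genesets(cfg, default_catalog.all_genes(),
                             planted_from=default_catalog.genes("AS"))
        assert all(15 <= len(db.genes_of(n)) <= 1000 for n in db.names())

    def test_zero_query_fraction_makes_planted_a_decoy(self, default_catalog):
        cfg = default_config(3)
        cfg = SyntheticConfig(**{**cfg.__dict__,
                                 "planted_pathway": cfg.planted_pathway.__class__(
                                     query_fraction=0.0)})
        db, _ = gen_genesets(cfg, default_catalog.all_genes(),
                             planted_from=default_catalog.genes("AS"))
        # no deliberate enrichment: overlap is whatever uniform sampling gives
        assert len(db.genes_of("SET_PLANTED")) == cfg.planted_pathway.size


class TestGenNetwork:
    def test_pure_planting_gives_complete_bipartite_connectivity(self):
        cfg = small_config()
        cfg = SyntheticConfig(**{**cfg.__dict__,
                                 "network_params": NetworkParams(
                                     n_nodes=60, p_background=0.0, p_planted=1.0,
                                     planted_pairs=(("AS", "CD"),))})
        cat = gen_catalog(cfg)
        net = build_network(gen_network(cfg, cat))
        a, b = deconfounded_pair(cat, "AS", "CD")
        assert connectivity(net, a, b) == len(a) * len(b)

    def test_planted_density_ordering_rejected_when_inverted(self):
        cfg = small_config()
        cfg = SyntheticConfig(**{**cfg.__dict__,
                                 "network_params": NetworkParams(
                                     p_background=0.5, p_planted=0.1)})
        with pytest.raises(ValueError):
            gen_network(cfg, gen_catalog(cfg))


class TestDeterminism:
    def test_identical_config_gives_byte_identical_files(self, tmp_path):
        cfg = small_config(seed=123)
        p1 = generate_all(cfg, tmp_path / "run1")
        p2 = generate_all(cfg, tmp_path / "run2")
        assert set(p1) == set(p2)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seed_changes_stochastic_outputs(self, tmp_path):
        a = generate_all(small_config(seed=1), tmp_path / "a")
        b = generate_all(small_config(seed=2), tmp_path / "b")
        assert a["variants"].read_bytes() != b["variants"].read_bytes()
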