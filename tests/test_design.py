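"""Fragmentation, patches, constrained shuffle and assembly."""

from collections import Counter

import pytest

from tolorf import (
    DesignConfig,
    Element,
    assemble,
    constrained_shuffle,
    design,
    make_patch,
    reverse_translate,
    split_gene,
    synth_reporter_orf,
    translate_cds,
)
from tolorf.errors import (
    AdjacencyError,
    ConfigError,
    ShuffleInfeasibleError,
    SplitOutOfRangeError,
    ValidationError,
)

from _oracles import valid_orders_by_enumeration


class TestSplitGene:
    @pytest.mark.parametrize("L,expected", [(10, (0, 5, 10)), (11, (0, 5, 11))])
    def test_default_midpoint_floor(self, L, expected):
        gene = synth_reporter_orf(L, seed=1, gene_id="g")
        n, c = split_gene(gene)
        assert n.codon_span == (expected[0], expected[1])
        assert c.codon_span == (expected[1], expected[2])

    def test_fragments_tile_stop_stripped_cds(self, toy_genes):
        for gene in toy_genes:
            n, c = split_gene(gene)
            assert n.nt + c.nt == gene.cds[:-3]
            assert translate_cds(n.nt) + translate_cds(c.nt) == gene.protein

    @pytest.mark.parametrize("s", [0, -1, 30, 31])
    def test_split_out_of_range(self, s):
        gene = synth_reporter_orf(30, seed=1, gene_id="g")
        with pytest.raises(SplitOutOfRangeError):
            split_gene(gene, s)

    def test_eight_genes_yield_sixteen_fragments(self, panel):
        frags = [f for g in panel for f in split_gene(g)]
        assert len(frags) == 16


class TestMakePatch:
    def test_central_split_full_width_is_60nt(self, panel):
        for gene in panel:
            s = gene.protein_length // 2
            patch = make_patch(gene, s, half_width=10)
            assert len(patch.nt) == 60

    def test_half_width_4_gives_24nt(self, toy_genes):
        gene = toy_genes[0]
        patch = make_patch(gene, gene.protein_length // 2, half_width=4)
        assert len(patch.nt) == 24

    def test_truncation_clamps_to_gene(self):
        gene = synth_reporter_orf(12, seed=3, gene_id="short")
        patch = make_patch(gene, 3, half_width=10)
        assert patch.codon_span == (0, 12)
        assert len(patch.nt) == 36

    def test_patch_sequence_is_parent_slice(self, toy_genes):
        gene = toy_genes[1]
        patch = make_patch(gene, 20, half_width=10)
        lo, hi = patch.codon_span
        assert patch.nt == gene.cds[3 * lo:3 * hi]


class TestConstrainedShuffle:
    def _elements(self, gene, split=None, half_width=10):
        n, c = split_gene(gene, split)
        patch = make_patch(gene, n.codon_span[1], half_width)
        return [Element.from_fragment(n), Element.from_fragment(c),
                Element.from_patch(patch)]

    def test_single_gene_infeasible_matches_enumeration(self, toy_genes):
        """Pigeonhole: 3 same-parent elements admit no valid permutation."""
        els = self._elements(toy_genes[0])
        assert valid_orders_by_enumeration([e.parent_id for e in els]) == []
        with pytest.raises(ShuffleInfeasibleError):
            constrained_shuffle(els, seed=0)

    def test_two_genes_valid_against_enumeration(self, toy_genes):
        els = self._elements(toy_genes[0]) + self._elements(toy_genes[1])
        valid = valid_orders_by_enumeration([e.parent_id for e in els])
        assert valid  # brute force: the valid set over all 720 orders is nonempty
        order = constrained_shuffle(els, seed=42)
        assert sorted(id(e) for e in order) == sorted(id(e) for e in els)
        for a, b in zip(order, order[1:]):
            assert a.parent_id != b.parent_id

    def test_determinism(self, toy_genes):
        els = self._elements(toy_genes[0]) + self._elements(toy_genes[1])
        o1 = constrained_shuffle(els, seed=7)
        o2 = constrained_shuffle(els, seed=7)
        assert o1 == o2

    def test_attempt_budget_exhaustion_raises(self, toy_genes):
        els = self._elements(toy_genes[0]) + self._elements(toy_genes[1])
        # feasible instance, but one attempt is very unlikely to succeed for
        # every seed; find a seed whose first shuffle is invalid and pin it
        for seed in range(100):
            try:
                constrained_shuffle(els, seed=seed, max_attempts=1)
            except ShuffleInfeasibleError:
                break
        else:  # pragma: no cover
            pytest.skip("every probed seed succeeded on the first attempt")


class TestAssemble:
    def test_length_arithmetic(self):
        """Construct length equals the independent sum of its parts."""
        g1 = synth_reporter_orf(20, seed=5, gene_id="a")
        g2 = synth_reporter_orf(30, seed=6, gene_id="b")
        config = DesignConfig(seed=3)
        construct, _, _ = design([g1, g2], config)
        expected = (
            3 * (20 + 30)               # fragment codons
            + 6 * 10 * 2                # two full-width patches
            + 3 * len(config.control_epitope_aa)
            + 3                         # stop
            + (3 if construct.atg_prepended else 0)
        )
        assert len(construct.nt) == expected

    def test_protein_ends_with_control_epitope(self, panel_design):
        _, construct, _, _ = panel_design
        assert construct.protein.endswith(construct.config.control_epitope_aa)

    def test_single_orf_invariants(self, panel_design):
        _, construct, _, _ = panel_design
        assert len(construct.nt) % 3 == 0
        assert construct.nt.startswith("ATG")
        assert construct.nt[-3:] == construct.config.stop_codon
        assert "*" not in construct.protein
        codons = [construct.nt[i:i + 3] for i in range(0, len(construct.nt), 3)]
        assert sum(c in ("TAA", "TAG", "TGA") for c in codons) == 1

    def test_codon_multiset_conservation(self, toy_design):
        """No junction creates or destroys a codon."""
        _, construct, _, _ = toy_design
        expected = Counter()
        for el in construct.elements:
            expected.update(el.nt[i:i + 3] for i in range(0, len(el.nt), 3))
        if construct.atg_prepended:
            expected.update(["ATG"])
        expected.update([construct.config.stop_codon])
        assert construct.codon_multiset() == expected

    def test_degenerate_passthrough_embeds_parent(self):
        gene = synth_reporter_orf(25, seed=9, gene_id="solo")
        el = Element(kind="fragment", nt=gene.cds[:-3], parent_id=gene.id,
                     codon_span=(0, 25), half="N")
        construct = assemble([el], DesignConfig(seed=0))
        assert gene.protein in construct.protein

    def test_adjacency_violation_rejected(self, toy_genes):
        from tolorf import split_gene

        n, c = split_gene(toy_genes[0])
        els = [Element.from_fragment(n), Element.from_fragment(c)]
        with pytest.raises(AdjacencyError):
            assemble(els, DesignConfig(seed=0))

    def test_junctions_mark_element_starts(self, toy_design):
        _, construct, _, _ = toy_design
        offset = 1 if construct.atg_prepended else 0
        expected = [1] if construct.atg_prepended else []
        pos = offset
        for el in construct.elements[:-1]:
            pos += el.n_codons
            expected.append(pos)
        assert list(construct.junctions) == expected


class TestDesignPipeline:
    def test_element_census(self, panel_design):
        _, construct, _, _ = panel_design
        kinds = Counter(e.kind for e in construct.elements)
        assert kinds == {"fragment": 16, "patch": 8, "control_epitope": 1}
        assert len(construct.elements) == 25

    def test_coverage_complete_under_defaults(self, panel_design):
        _, construct, coverage, _ = panel_design
        assert coverage.complete
        for k in range(8, 12):
            for parent in coverage.per_parent:
                assert not coverage.per_parent[parent][k].missing

    def test_narrow_patch_loses_kmers_at_split(self, toy_genes):
        config = DesignConfig(seed=4, patch_half_width=3)
        construct, coverage, _ = design(toy_genes, config)
        assert not coverage.complete
        for gene in toy_genes:
            s = gene.protein_length // 2
            for k in range(8, 12):
                for pep, positions in coverage.per_parent[gene.id][k].missing.items():
                    for p in positions:
                        assert s - k + 1 <= p <= s - 1  # straddles the split

    def test_byte_identical_across_runs(self, panel):
        c1, _, _ = design(panel, DesignConfig(seed=99))
        c2, _, _ = design(panel, DesignConfig(seed=99))
        assert c1.nt == c2.nt
        assert c1.elements == c2.elements

    def test_fewer_than_two_genes_rejected(self, toy_genes):
        with pytest.raises(ValidationError):
            design(toy_genes[:1], DesignConfig(seed=0))

    def test_report_records_run(self, panel_design):
        panel, construct, _, report = panel_design
        assert report.seed == 11
        assert report.n_genes == 8
        assert set(report.split_codons) == {g.id for g in panel}
        assert report.construct_length_nt == len(construct.nt)
        table = report.to_frame()
        assert len(table) == len(construct.feature_table())


class TestReverseTranslate:
    @pytest.mark.parametrize("aa,nt", [("M", "ATG"), ("W", "TGG")])
    def test_unique_codons(self, aa, nt):
        assert reverse_translate(aa) == nt

    def test_section_property(self):
        aa = "ARNDCQEGHILKMFPSTWYV"
        assert translate_cds(reverse_translate(aa)) == aa

    def test_unknown_letter(self):
        with pytest.raises(ValidationError):
            reverse_translate("MBX")


class TestDesignConfig:
    def test_defaults_give_60nt_patch(self):
        config = DesignConfig(seed=0)
        assert config.k_max == 11
        assert config.half_width == 10  # => 6 * 10 = 60 nt full patch

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_min": 0}, {"k_min": 12, "k_max": 11},
            {"patch_half_width": 0}, {"stop_codon": "AAA"},
            {"adjacency": "loose"}, {"control_epitope_aa": ""},
            {"control_epitope_nt": "ATGATG"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            DesignConfig(seed=0, **kwargs)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("k_min: 9\nk_max: 12\nseed: 5\nstop_codon: TGA\n")
        config = DesignConfig.from_yaml(path, seed=8)
        assert (config.k_min, config.k_max) == (9, 12)
        assert config.seed == 8  # override wins
        assert config.stop_codon == "TGA"
        assert config.half_width == 11
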