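import numpy as np
import pytest

from minicrkit import NamedSpacer, NucSeq, assemble_minicr
from minicrkit.assembly import ArraySpacer, Backbone, MiniCRConstruct
from minicrkit.errors import (
    AssemblyError,
    FusionAmbiguityError,
    NoAmpliconError,
    PrimerDesignError,
)
from minicrkit.oepcr import (
    design_dosage_route,
    design_flank_unit,
    design_m_primers,
    design_moe_primers,
    design_oe_units,
    simulate_megaprimer_insertion,
    simulate_oe_fusion,
    simulate_primer_extension,
)

from conftest import random_dna


def make_template(backbone: Backbone, context_seed: int = 500, context_len: int = 400) -> NucSeq:
    """Circular plasmid carrying the intact backbone locus plus vector context."""
    locus = MiniCRConstruct(
        name="template",
        leader_seq=backbone.leader_seq,
        repeat_seq=backbone.repeat_seq,
        spacers=[ArraySpacer(s.name, s.seq, "backbone") for s in backbone.spacers],
    )
    return NucSeq(id="pEntry", seq=locus.full_seq + random_dna(context_len, context_seed),
                  topology="circular")


class TestFlankUnit:
    def test_geometry_37nt_spacers_24nt_repeat(self):
        left, right = random_dna(37, 1), random_dna(37, 2)
        repeat = random_dna(24, 3)
        unit = design_flank_unit(left, repeat, right, overlap=12)
        assert len(unit.fw_primer.seq) == 55  # 37 + 18
        assert len(unit.rv_primer.seq) == 55  # 18 + 37
        assert len(unit.product) == 98  # 37 + 24 + 37
        assert unit.product == left + repeat + right

    def test_extension_oracle_reproduces_product(self):
        left, right, repeat = random_dna(30, 4), random_dna(40, 5), random_dna(26, 6)
        unit = design_flank_unit(left, repeat, right, overlap=14)
        assert simulate_primer_extension(unit.fw_primer.seq, unit.rv_primer.seq,
                                         min_overlap=14) == unit.product

    def test_overlap_exceeding_repeat_rejected(self):
        with pytest.raises(PrimerDesignError, match="overlap"):
            design_flank_unit(random_dna(37, 1), random_dna(24, 2), random_dna(37, 3),
                              overlap=30)


class TestMoeAndMPrimers:
    def test_50nt_total_with_26nt_arm(self, backbone, five_spacers):
        moe = design_moe_primers(backbone, five_spacers[0].seq, five_spacers[-1].seq)
        assert len(moe.moe_fw.seq) == 50
        assert len(moe.moe_rv.seq) == 50
        assert moe.moe_fw.arm_len == 50 - len(backbone.repeat_seq) == 26

    def test_moe_fw_3prime_anneals_to_repeat(self, backbone, five_spacers):
        moe = design_moe_primers(backbone, five_spacers[0].seq, five_spacers[-1].seq)
        assert moe.moe_fw.seq.endswith(backbone.repeat_seq)

    def test_infeasible_total_length(self, backbone, five_spacers):
        with pytest.raises(PrimerDesignError, match="arm"):
            design_moe_primers(backbone, five_spacers[0].seq, five_spacers[-1].seq,
                               total_length=30)

    def test_m_primers_are_arm_segments(self, backbone, five_spacers):
        moe = design_moe_primers(backbone, five_spacers[0].seq, five_spacers[-1].seq)
        m_fw, m_rv = design_m_primers(moe.moe_fw, moe.moe_rv)
        assert moe.moe_fw.seq.startswith(m_fw.seq)
        assert moe.moe_rv.seq.startswith(m_rv.seq)
        assert len(m_fw.seq) == len(m_rv.seq) == 26


class TestFusion:
    def test_three_unit_fragment_length(self, backbone):
        """D1arm|R|S1 + S1|R|S2 + S2|R|D5arm -> 26+24+37+24+37+24+26 = 198 nt."""
        s1, s2 = random_dna(37, 11), random_dna(37, 12)
        units, m_primers, moe = design_oe_units(backbone, [s1, s2])
        frag = simulate_oe_fusion(units, m_primers)
        assert len(frag.seq) == 198
        assert frag.seq == moe.d1_arm + backbone.repeat_seq + s1 + backbone.repeat_seq \
            + s2 + backbone.repeat_seq + moe.d5_arm
        assert frag.unit_trace == ["terminal_left", "S1-S2", "terminal_right"]

    def test_single_spacer_two_terminal_units(self, backbone):
        units, m_primers, _ = design_oe_units(backbone, [random_dna(37, 13)])
        frag = simulate_oe_fusion(units, m_primers)
        assert frag.unit_trace == ["terminal_left", "terminal_right"]

    def test_duplicate_inner_spacer_is_ambiguous(self, backbone):
        s = random_dna(37, 14)
        units, m_primers, _ = design_oe_units(backbone, [s, s, s])
        with pytest.raises(FusionAmbiguityError, match="dosage"):
            simulate_oe_fusion(units, m_primers)

    def test_distinct_spacers_never_ambiguous(self, backbone):
        for seed in range(5):
            spacers = [random_dna(37, 200 + 10 * seed + i) for i in range(4)]
            units, m_primers, _ = design_oe_units(backbone, spacers)
            simulate_oe_fusion(units, m_primers)  # must not raise

    def test_missing_terminal_arm_gives_no_amplicon(self, backbone):
        units, m_primers, _ = design_oe_units(backbone, [random_dna(37, 15),
                                                         random_dna(37, 16)])
        with pytest.raises(NoAmpliconError):
            simulate_oe_fusion(units[1:], m_primers)  # left terminal unit removed

    def test_disconnected_unit_detected(self, backbone):
        units, m_primers, _ = design_oe_units(backbone, [random_dna(37, 17)])
        stray = design_flank_unit(random_dna(37, 18), backbone.repeat_seq,
                                  random_dna(37, 19), name="stray")
        with pytest.raises(NoAmpliconError, match="disconnected"):
            simulate_oe_fusion(units + [stray], m_primers)

    def test_fusion_is_order_independent(self, backbone):
        spacers = [random_dna(37, 20 + i) for i in range(4)]
        units, m_primers, _ = design_oe_units(backbone, spacers)
        frag = simulate_oe_fusion(units, m_primers)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(rng.permutation(len(units)))
            again = simulate_oe_fusion([units[i] for i in shuffled], m_primers)
            assert again.seq == frag.seq


class TestMegaprimerInsertion:
    def test_end_to_end_round_trip_matches_direct_assembly(self, backbone, five_spacers):
        units, m_primers, _ = design_oe_units(backbone, five_spacers)
        frag = simulate_oe_fusion(units, m_primers)
        template = make_template(backbone)
        product = simulate_megaprimer_insertion(frag, template)
        expected = assemble_minicr(backbone, five_spacers)
        assert expected.full_seq in product.seq + product.seq  # circular containment
        assert product.topology == "circular"

    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_over_random_backbones(self, seed):
        """Route independence over >= 50 random backbone/spacer sets."""
        rng = np.random.default_rng(1000 + seed)
        mk = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        backbone = Backbone.from_sequences(mk(80), mk(24), [mk(37) for _ in range(6)])
        n_new = int(rng.integers(1, 6))
        spacers = [NamedSpacer(f"S{i+1}", mk(37)) for i in range(n_new)]
        units, m_primers, _ = design_oe_units(backbone, spacers)
        frag = simulate_oe_fusion(units, m_primers)
        template = make_template(backbone, context_seed=2000 + seed)
        product = simulate_megaprimer_insertion(frag, template)
        expected = assemble_minicr(backbone, spacers)
        assert expected.full_seq in product.seq + product.seq

    def test_product_length_arithmetic(self, backbone, five_spacers):
        units, m_primers, _ = design_oe_units(backbone, five_spacers[:2])
        frag = simulate_oe_fusion(units, m_primers)
        template = make_template(backbone)
        product = simulate_megaprimer_insertion(frag, template)
        arm_l = frag.seq[: frag.left_arm_len]
        arm_r = frag.seq[-frag.right_arm_len :]
        i1 = template.seq.find(arm_l)
        i2 = template.seq.find(arm_r)
        replaced_span = (i2 + frag.right_arm_len) - i1
        assert len(product.seq) == len(template.seq) - replaced_span + len(frag.seq)

    def test_missing_arm_is_an_error(self, backbone, five_spacers):
        units, m_primers, _ = design_oe_units(backbone, five_spacers[:1])
        frag = simulate_oe_fusion(units, m_primers)
        bare = NucSeq(id="bare", seq=random_dna(600, 300), topology="circular")
        with pytest.raises(AssemblyError, match="arm absent"):
            simulate_megaprimer_insertion(frag, bare)

    def test_duplicate_arm_site_is_an_error(self, backbone, five_spacers):
        units, m_primers, _ = design_oe_units(backbone, five_spacers[:1])
        frag = simulate_oe_fusion(units, m_primers)
        template = make_template(backbone)
        doubled_site = NucSeq(id="dup", seq=template.seq + frag.seq[: frag.left_arm_len],
                              topology="circular")
        with pytest.raises(AssemblyError, match="occurs 2 times"):
            simulate_megaprimer_insertion(frag, doubled_site)

    def test_linear_template_rejected(self, backbone, five_spacers):
        units, m_primers, _ = design_oe_units(backbone, five_spacers[:1])
        frag = simulate_oe_fusion(units, m_primers)
        linear = NucSeq(id="lin", seq=make_template(backbone).seq, topology="linear")
        with pytest.raises(AssemblyError, match="circular"):
            simulate_megaprimer_insertion(frag, linear)


class TestDosageRoute:
    def test_triple_copy_product_structure(self, backbone, five_spacers):
        single = assemble_minicr(backbone, [five_spacers[1]], name="single")
        design = design_dosage_route(single, "AA2", copies=3)
        names = [s.name for s in design.product.spacers]
        assert names == ["D1", "AA2", "AA2", "AA2", "D5", "D6"]
        spacer, repeat = five_spacers[1].seq, backbone.repeat_seq
        assert (spacer + repeat + spacer + repeat + spacer) in design.product.full_seq

    def test_over_primer_is_80nt_for_37nt_spacer(self, backbone, five_spacers):
        single = assemble_minicr(backbone, [five_spacers[1]])
        design = design_dosage_route(single, "AA2", copies=3)
        # half-spacer (19) + repeat (24) + full spacer (37)
        assert len(design.over_fw.seq) == 80
        assert len(design.over_rv.seq) == 80

    def test_lin_primers_split_spacer_at_midpoint(self, backbone, five_spacers):
        from minicrkit import revcomp

        spacer = five_spacers[1].seq
        single = assemble_minicr(backbone, [five_spacers[1]])
        design = design_dosage_route(single, "AA2", copies=2)
        mid = len(spacer) // 2
        assert design.lin_fw.seq == spacer[mid:]
        assert design.lin_rv.seq == revcomp(spacer[:mid])

    def test_copies_1_is_identity(self, backbone, five_spacers):
        single = assemble_minicr(backbone, [five_spacers[0]])
        assert design_dosage_route(single, "AA1", 1).product is single

    def test_route_independence_vs_direct_assembly(self, backbone, five_spacers):
        sp = five_spacers[1]
        single = assemble_minicr(backbone, [sp])
        routed = design_dosage_route(single, "AA2", copies=3).product
        direct = assemble_minicr(backbone, [sp, sp, sp])
        assert routed.full_seq == direct.full_seq

    def test_absent_or_duplicated_spacer_rejected(self, backbone, five_spacers):
        single = assemble_minicr(backbone, [five_spacers[0]])
        with pytest.raises(AssemblyError, match="not found"):
            design_dosage_route(single, "nope", 2)
        double = assemble_minicr(backbone, [five_spacers[0], five_spacers[0]])
        with pytest.raises(AssemblyError, match="occurs 2 times"):
            design_dosage_route(double, "AA1", 2)


def test_primer_3prime_ends_anneal_in_simulation(backbone, five_spacers):
    """Every designed primer's 3'-terminal 12 nt match its intended template."""
    units, m_primers, moe = design_oe_units(backbone, five_spacers)
    frag = simulate_oe_fusion(units, m_primers)
    from minicrkit import revcomp

    for unit in units:
        assert unit.fw_primer.seq[-12:] in unit.product
        assert unit.rv_primer.seq[-12:] in revcomp(unit.product)
    assert m_primers[0].seq[-12:] in frag.seq
    assert m_primers[1].seq[-12:] in revcomp(frag.seq)
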