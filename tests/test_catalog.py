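import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from famsurvey.catalog import (
    SequenceError,
    WATER_MW,
    build_catalog,
    classify_subfamily,
    instability_index,
    isoelectric_point,
    molecular_weight,
    net_charge,
    protein_properties,
    scan_wd40_repeats,
    select_representative,
)
from famsurvey.io import DomainHit, GeneModel

from oracles import instability_index_naive, scan_repeats_bruteforce

CONSENSUS = "GECKXVLXGHTSTVTCVAFSPDGPLLASGSRDGTIKIWD"


class TestRepeatScan:
    def test_consensus_repeat_located(self):
        # hand-indexed: GH at residues 9-10, WD at 38-39, 27 residues between
        assert scan_wd40_repeats(CONSENSUS) == [(9, 39)]

    def test_no_tryptophan_no_repeat(self):
        assert scan_wd40_repeats("GHAAAAAAAAAAAAAAAAAAAAAAAAAAAAA") == []

    def test_separation_window_bounds(self):
        # separation exactly min_sep and max_sep are both accepted
        lo = "GH" + "A" * 20 + "WD"
        hi = "GH" + "A" * 50 + "WD"
        out = "GH" + "A" * 51 + "WD"
        assert scan_wd40_repeats(lo) == [(1, len(lo))]
        assert scan_wd40_repeats(hi) == [(1, len(hi))]
        assert scan_wd40_repeats(out) == []

    def test_illegal_residue_rejected(self):
        with pytest.raises(SequenceError):
            scan_wd40_repeats("GH123WD")

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        alphabet = list("GHWDASTV")  # enriched in anchor letters
        for _ in range(300):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(10, 120))))
            assert scan_wd40_repeats(seq) == scan_repeats_bruteforce(seq)


class TestRepresentative:
    @pytest.mark.parametrize(
        "transcripts,expected",
        [
            ({"t1": 300, "t2": 280}, "t1"),
            ({"t2": 300, "t1": 300}, "t1"),  # tie -> lexicographically smallest
            ({"only": 91}, "only"),
        ],
    )
    def test_longest_then_lexicographic(self, transcripts, expected):
        assert select_representative(transcripts) == expected

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError):
            select_representative({})


class TestSubfamilies:
    @pytest.mark.parametrize(
        "domains,expected",
        [
            ({"WD40"}, "A"),
            ({"WD40", "LisH"}, "B"),
            ({"WD40", "Utp13"}, "C"),
            ({"WD40", "WDAD"}, "D"),
            ({"WD40", "COPI-alpha-C"}, "D"),
            ({"WD40", "RBBP4"}, "E"),
            ({"WD40", "NLE"}, "F"),
            ({"WD40", "Pkinase"}, "G"),
            ({"WD40", "HEAT"}, "G"),
            ({"WD40", "BEACH"}, "H"),
            ({"WD40", "zf-C3HC4"}, "I"),
            ({"WD40", "BCAS3"}, "J"),
            ({"WD40", "F-box"}, "K"),
            ({"WD40", "U-box"}, "K"),
            ({"WD40", "DUF1899"}, "K"),
        ],
    )
    def test_rule_table(self, domains, expected):
        assert classify_subfamily(domains) == expected

    def test_missing_family_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_subfamily({"LisH"})

    def test_two_diagnostic_domains_flagged_ambiguous(self):
        label, ambiguous = classify_subfamily(
            {"WD40", "LisH", "zf-C3HC4"}, with_ambiguity=True
        )
        assert label == "B" and ambiguous

    def test_total_on_random_domain_sets(self):
        rng = np.random.default_rng(0)
        pool = ["LisH", "Utp12", "WDAD", "NLE", "BEACH", "F-box", "Unknown1", "zf-X"]
        for _ in range(100):
            extra = set(rng.choice(pool, size=int(rng.integers(0, 4)), replace=False))
            label = classify_subfamily({"WD40"} | extra)
            assert label in set("ABCDEFGHIJK")


class TestProteinProperties:
    def test_glycine_molecular_weight(self):
        # glycine residue mass + one water, summed by hand
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_mw_additivity_exact(self):
        a, b = "MKVLAT", "GHWDPE"
        assert molecular_weight(a + b) == pytest.approx(
            molecular_weight(a) + molecular_weight(b) - WATER_MW, abs=1e-9
        )

    def test_net_charge_vanishes_at_pi(self):
        for seq in ["MKVLAT", "DDDDEE", "RRKKH", "GAVLIX"]:
            assert abs(net_charge(seq, isoelectric_point(seq))) < 1e-4

    def test_pi_monotone_in_charged_residues(self):
        base = "MKVLATGS"
        assert isoelectric_point(base + "D") <= isoelectric_point(base)
        assert isoelectric_point(base + "R") >= isoelectric_point(base)

    def test_instability_gg_matches_dipeptide_loop(self):
        assert instability_index("GG") == pytest.approx(
            instability_index_naive("GG"), abs=1e-12
        )

    def test_instability_matches_naive_oracle_random(self):
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            seq = "".join(rng.choice(aas, size=int(rng.integers(2, 200))))
            assert instability_index(seq) == pytest.approx(
                instability_index_naive(seq), abs=1e-9
            )

    def test_agrees_with_biopython_reference(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            seq = "".join(rng.choice(aas, size=100))
            pa = ProteinAnalysis(seq)
            assert molecular_weight(seq) == pytest.approx(pa.molecular_weight(), abs=0.1)
            assert instability_index(seq) == pytest.approx(pa.instability_index(), abs=0.01)
            # pKa sets differ slightly at the termini; agreement is loose
            assert isoelectric_point(seq) == pytest.approx(pa.isoelectric_point(), abs=0.35)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SequenceError):
            protein_properties("")
        with pytest.raises(SequenceError):
            instability_index("G")


class TestBuildCatalog:
    def _models(self):
        return [
            GeneModel("g3", "chr1", 90_000, 91_000, "+", [("g3.1", 40)]),
            GeneModel("g1", "chr1", 10_000, 11_000, "+", [("g1.1", 40)]),
            GeneModel("g2", "chr1", 50_000, 51_000, "-", [("g2.1", 40)]),
        ]

    def test_ordinal_naming_by_position(self):
        seq = "GH" + "A" * 25 + "WD" + "A" * 11
        proteins = {f"g{i}.1": seq for i in (1, 2, 3)}
        hits = [DomainHit(f"g{i}.1", "WD40", 1, 29, "smart") for i in (1, 2, 3)]
        members = build_catalog(self._models(), proteins, hits)
        assert [(m.name, m.gene_id) for m in members] == [
            ("FAM-1", "g1"), ("FAM-2", "g2"), ("FAM-3", "g3")
        ]

    def test_single_scanner_evidence_suffices(self):
        seq = "GH" + "A" * 25 + "WD" + "A" * 11
        proteins = {"g1.1": seq, "g2.1": seq, "g3.1": seq}
        hits = [DomainHit("g1.1", "WD40", 1, 29, "smart")]  # smart only, one gene
        members = build_catalog(self._models(), proteins, hits)
        assert [m.gene_id for m in members] == ["g1"]

    def test_builtin_detector_membership(self):
        seq = "GH" + "A" * 25 + "WD" + "A" * 11
        proteins = {"g1.1": seq, "g2.1": "A" * 40, "g3.1": "A" * 40}
        members = build_catalog(self._models(), proteins, [], builtin_detector=True)
        assert [m.gene_id for m in members] == ["g1"]
        assert members[0].repeat_hits == [(1, 29)]

    def test_synthetic_membership_and_subfamilies_exact(self, dataset):
        members = build_catalog(
            dataset.gene_models, dataset.proteins, dataset.domain_hits
        )
        truth = dataset.truth
        assert {m.gene_id for m in members} == truth.family_gene_ids
        assert all(m.subfamily == truth.subfamily_of[m.gene_id] for m in members)
        # names follow pseudomolecule order
        starts = [(m.chromosome, m.start) for m in members]
        assert starts == sorted(starts)
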