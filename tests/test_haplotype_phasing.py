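import numpy as np
import pandas as pd
import pytest

from perizygote import haplotype_phasing as hp
from perizygote.records import CnvEvent, MATERNAL, PATERNAL, UNASSIGNED, UNPHASED

from conftest import make_trio_table


def informative_fixture(n_pat, n_mat, chrom="chr1", start=1000, step=100):
    """Informative sites: first n_pat with paternal alt, then n_mat maternal."""
    rows = []
    pos = start
    for _ in range(n_pat):
        rows.append({"pos": pos, "father_gt": "1/1", "mother_gt": "0/0",
                     "father_ad": (0, 30)})
        pos += step
    for _ in range(n_mat):
        rows.append({"pos": pos, "father_gt": "0/0", "mother_gt": "1/1",
                     "mother_ad": (0, 30)})
        pos += step
    return make_trio_table([{**r, "chrom": chrom} for r in rows])


class TestInformativeSites:
    @pytest.mark.parametrize(
        "father,mother,expected",
        [
            ("1/1", "0/0", PATERNAL),
            ("0/0", "0/1", MATERNAL),
            ("0/1", "0/0", PATERNAL),
            ("1/1", "0/1", PATERNAL),  # mother must donate her 0
            ("0/1", "1/1", MATERNAL),  # father must donate his 0
        ],
    )
    def test_forced_configurations(self, father, mother, expected):
        table = make_trio_table([{"father_gt": father, "mother_gt": mother}])
        out = hp.informative_sites(table)
        assert list(out["alt_origin"]) == [expected]

    @pytest.mark.parametrize("father,mother", [("0/1", "0/1"), ("1/1", "1/1")])
    def test_ambiguous_configurations_dropped(self, father, mother):
        table = make_trio_table([{"father_gt": father, "mother_gt": mother}])
        assert len(hp.informative_sites(table)) == 0

    def test_mendelian_violation_logged(self):
        table = make_trio_table([{"father_gt": "0/0", "mother_gt": "0/0"}])
        out = hp.informative_sites(table)
        assert len(out) == 0
        assert len(out.attrs["mendelian_violations"]) == 1

    def test_homozygous_child_not_informative(self):
        table = make_trio_table(
            [{"child_gt": "1/1", "father_gt": "0/1", "mother_gt": "0/1"}]
        )
        assert len(hp.informative_sites(table)) == 0


def block_from(informative, hap_a_carries_alt):
    """Block sites covering the informative table; hap_a carries the alt
    allele at each site iff the flag says so."""
    return pd.DataFrame(
        {
            "chrom": informative["chrom"],
            "pos": informative["pos"],
            "block_id": 0,
            "hap_a": 1 if hap_a_carries_alt else 0,
            "hap_b": 0 if hap_a_carries_alt else 1,
        }
    )


class TestAssignBlockOrigin:
    def test_strong_majority_assigned(self):
        informative = hp.informative_sites(informative_fixture(24, 1))
        block = block_from(informative, hap_a_carries_alt=True)
        out = hp.assign_block_origin(block, informative)
        assert out.hap_a_origin == PATERNAL
        assert out.n_informative == 25
        assert out.consistency == pytest.approx(0.96)

    def test_nineteen_sites_unassigned(self):
        informative = hp.informative_sites(informative_fixture(19, 0))
        block = block_from(informative, True)
        out = hp.assign_block_origin(block, informative)
        assert out.hap_a_origin == UNASSIGNED
        assert out.n_informative == 19 and out.consistency == 1.0

    def test_twenty_sites_all_consistent_assigned(self):
        informative = hp.informative_sites(informative_fixture(20, 0))
        out = hp.assign_block_origin(block_from(informative, True), informative)
        assert out.hap_a_origin == PATERNAL

    def test_085_consistency_unassigned(self):
        informative = hp.informative_sites(informative_fixture(17, 3))
        out = hp.assign_block_origin(block_from(informative, True), informative)
        assert out.hap_a_origin == UNASSIGNED
        assert out.consistency == pytest.approx(0.85)

    def test_exactly_090_consistency_assigned(self):
        informative = hp.informative_sites(informative_fixture(18, 2))
        out = hp.assign_block_origin(block_from(informative, True), informative)
        assert out.hap_a_origin == PATERNAL
        assert out.consistency == pytest.approx(0.9)

    def test_tie_unassigned(self):
        informative = hp.informative_sites(informative_fixture(10, 10))
        out = hp.assign_block_origin(block_from(informative, True), informative)
        assert out.hap_a_origin == UNASSIGNED

    def test_relabeling_symmetry(self):
        informative = hp.informative_sites(informative_fixture(24, 1))
        a = hp.assign_block_origin(block_from(informative, True), informative)
        b = hp.assign_block_origin(block_from(informative, False), informative)
        assert a.hap_a_origin == PATERNAL and b.hap_a_origin == MATERNAL
        assert a.origin_of("B") == b.origin_of("A") == MATERNAL

    def test_threshold_monotonicity(self, rng):
        """Raising the consistency threshold never assigns more blocks."""
        blocks = []
        for b in range(25):
            n_pat = int(rng.integers(0, 30))
            n_mat = int(rng.integers(0, 30))
            trio = informative_fixture(n_pat, n_mat, start=1000 + 100_000 * b)
            informative = hp.informative_sites(trio)
            blocks.append((block_from(informative, True), informative))
        counts = []
        for thr in (0.6, 0.8, 0.9, 0.95, 1.0):
            assigned = sum(
                hp.assign_block_origin(sites, inf, min_consistency=thr).hap_a_origin
                != UNASSIGNED
                for sites, inf in blocks
            )
            counts.append(assigned)
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the sweep actually discriminates


class TestPhaseDnm:
    def test_dnm_on_assigned_haplotype(self):
        informative = hp.informative_sites(informative_fixture(25, 0))
        assignments = {0: hp.assign_block_origin(block_from(informative, True), informative)}
        assert hp.phase_dnm(0, "A", assignments) == PATERNAL
        assert hp.phase_dnm(0, "B", assignments) == MATERNAL

    def test_outside_blocks_unphased(self):
        assert hp.phase_dnm(-1, None, {}) == UNPHASED
        assert hp.phase_dnm(5, "A", {}) == UNPHASED

    def test_invalid_haplotype_label(self):
        with pytest.raises(ValueError):
            hp.phase_dnm(0, "C", {0: hp.PhaseAssignment(0, PATERNAL, 25, 1.0)})

    def test_simulation_origin_agreement(self, default_sim):
        """With error-free blocks, phased de novo mutations recover the
        true parental origin."""
        sim = default_sim
        informative = hp.informative_sites(sim.variants)
        block_sites = sim.truth.block_sites.rename(columns={"pos0": "pos"}).copy()
        block_sites["pos"] += 1
        assignments = hp.assign_all_blocks(block_sites, informative)
        phased = hp.phase_dnm_table(sim.truth.dnms, assignments)
        mask = phased != UNPHASED
        assert mask.sum() >= 30
        agreement = (phased[mask] == sim.truth.dnms.loc[mask, "parent"]).mean()
        assert agreement >= 0.98

    def test_phased_fraction_matches_assigned_blocks(self, default_sim):
        """Every mutation inside an assigned block is phased; every one
        outside (or in an unassigned block) is not."""
        sim = default_sim
        informative = hp.informative_sites(sim.variants)
        block_sites = sim.truth.block_sites.rename(columns={"pos0": "pos"}).copy()
        block_sites["pos"] += 1
        assignments = hp.assign_all_blocks(block_sites, informative)
        phased = hp.phase_dnm_table(sim.truth.dnms, assignments)
        expect_phased = sim.truth.dnms["block_id"].map(
            lambda b: b >= 0
            and assignments.get(b) is not None
            and assignments[b].hap_a_origin != UNASSIGNED
        )
        assert ((phased != UNPHASED) == expect_phased).all()


class TestPhaseDnCnv:
    def test_shifted_site_identifies_duplicated_allele(self):
        cnv = CnvEvent("chr1", 1000, 2000, "DUP")
        sites = pd.DataFrame(
            [{"pos": 1500, "ref_depth": 20, "alt_depth": 40, "alt_origin": PATERNAL}]
        )
        assert hp.phase_dncnv(cnv, sites) == PATERNAL

    def test_shifted_reference_allele_flips_origin(self):
        cnv = CnvEvent("chr1", 1000, 2000, "DUP")
        sites = pd.DataFrame(
            [{"pos": 1500, "ref_depth": 40, "alt_depth": 20, "alt_origin": PATERNAL}]
        )
        assert hp.phase_dncnv(cnv, sites) == MATERNAL

    def test_balanced_sites_unassigned(self):
        cnv = CnvEvent("chr1", 1000, 2000, "DUP")
        sites = pd.DataFrame(
            [
                {"pos": p, "ref_depth": 30, "alt_depth": 30, "alt_origin": PATERNAL}
                for p in (1100, 1500, 1900)
            ]
        )
        assert hp.phase_dncnv(cnv, sites) == UNASSIGNED

    def test_non_duplication_rejected(self):
        cnv = CnvEvent("chr1", 1000, 2000, "DEL")
        with pytest.raises(ValueError):
            hp.phase_dncnv(cnv, pd.DataFrame(columns=["pos", "ref_depth", "alt_depth", "alt_origin"]))

    def test_simulation_round_trip_all_duplications(self, default_sim):
        """All planted duplications get the correct parent of origin from
        intra-duplication allele ratios."""
        sim = default_sim
        informative = hp.informative_sites(sim.variants)
        child_het = sim.variants[sim.variants["child_gt"] == "0/1"]
        het = child_het.merge(informative, on=["chrom", "pos"]).rename(
            columns={"child_ref": "ref_depth", "child_alt": "alt_depth"}
        )
        correct = 0
        for cnv in sim.truth.cnvs:
            origin = hp.phase_dncnv(cnv, het[het["chrom"] == cnv.chrom])
            correct += origin == cnv.parent_of_origin
        assert correct == len(sim.truth.cnvs)
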