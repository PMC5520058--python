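import io
import itertools

import numpy as np
import pytest

from paleodog import simdata
from paleodog.damagefit import DamageModel
from paleodog.damcall import (
    GENOTYPES,
    GenotypeLikelihoods,
    PileupSite,
    PileupParseError,
    call_region,
    call_site,
    read_pileup,
    site_likelihoods,
    write_vcf,
)
from conftest import make_stack


def brute_force_loglik(site: PileupSite, damage: DamageModel | None) -> np.ndarray:
    """Independent per-read product oracle for the damage-aware likelihood.

    Enumerates, per read and per true allele, the full damage-then-error
    probability by explicit summation over intermediate template bases.
    """
    bases = "ACGT"
    out = np.zeros(10)
    keep = (site.mapqs >= 15) & (site.quals >= 15) & (site.bases != "N")
    for gi, (a1, a2) in enumerate(GENOTYPES):
        total = 0.0
        for r in np.flatnonzero(keep):
            eps = 10.0 ** (-min(site.quals[r], 40) / 10.0)
            per_allele = {}
            for allele in {a1, a2}:
                p = 0.0
                for template in bases:
                    # damage distribution of the template given the true allele
                    if site.orients[r] > 0:
                        d_ct = damage.five_prime.probability(site.pos5[r]) if damage else 0.0
                        d_ga = damage.three_prime.probability(site.pos3[r]) if damage else 0.0
                    else:
                        d_ct = damage.three_prime.probability(site.pos3[r]) if damage else 0.0
                        d_ga = damage.five_prime.probability(site.pos5[r]) if damage else 0.0
                    if allele == "C":
                        p_dam = {"T": d_ct, "C": 1 - d_ct}.get(template, 0.0)
                    elif allele == "G":
                        p_dam = {"A": d_ga, "G": 1 - d_ga}.get(template, 0.0)
                    else:
                        p_dam = 1.0 if template == allele else 0.0
                    p_err = (1 - eps) if site.bases[r] == template else eps / 3.0
                    p += p_dam * p_err
                per_allele[allele] = p
            total += np.log(0.5 * per_allele[a1] + 0.5 * per_allele[a2])
        out[gi] = total
    return out


def make_site(bases, ref="C", **kw):
    return PileupSite(chrom="1", pos=100, ref=ref, **make_stack(bases, **kw))


def gt_index(a, b):
    return GENOTYPES.index(tuple(sorted((a, b))))


class TestSiteLikelihoods:
    def test_clean_homozygote_ordering(self):
        site = make_site("C" * 10)
        lik = site_likelihoods(site, DamageModel.flat(0.0))
        ll = lik.loglik
        assert np.argmax(ll) == gt_index("C", "C")
        assert ll[gt_index("C", "C")] > ll[gt_index("C", "T")] > ll[gt_index("T", "T")]
        assert lik.effective_depth == 10

    def test_matches_brute_force_oracle(self, std_damage_model):
        # 8 C reads + 2 T reads, all at 5' position 1 of forward reads
        site = make_site("CCCCCCCCTT", quals=40, pos5=1)
        lik = site_likelihoods(site, std_damage_model)
        oracle = brute_force_loglik(site, std_damage_model)
        assert np.allclose(lik.loglik, oracle, atol=1e-10, rtol=0)

    def test_oracle_on_mixed_orientations(self, std_damage_model):
        rng = np.random.default_rng(0)
        n = 12
        site = PileupSite(
            chrom="1", pos=5, ref="G",
            bases=rng.choice(list("ACGT"), n),
            quals=rng.integers(10, 45, n),
            mapqs=rng.integers(10, 60, n),
            orients=rng.choice([1, -1], n),
            pos5=rng.integers(1, 20, n),
            pos3=rng.integers(1, 20, n),
        )
        lik = site_likelihoods(site, std_damage_model)
        oracle = brute_force_loglik(site, std_damage_model)
        assert np.allclose(lik.loglik, oracle, atol=1e-10, rtol=0)

    def test_damage_naive_prefers_het_on_damaged_stack(self, std_damage_model):
        """The false-heterozygote mechanism the damage-aware caller suppresses."""
        site = make_site("CCCCCCCCTT", quals=40, pos5=1)
        aware = site_likelihoods(site, std_damage_model).loglik
        naive = site_likelihoods(site, DamageModel.flat(0.0)).loglik
        cc, ct = gt_index("C", "C"), gt_index("C", "T")
        assert naive[ct] > naive[cc]
        assert aware[cc] > aware[ct]

    def test_zero_amplitude_equals_standard_caller(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(1, 15))
            site = PileupSite(
                chrom="1", pos=1, ref="A",
                bases=rng.choice(list("ACGT"), n),
                quals=rng.integers(0, 50, n),
                mapqs=rng.integers(0, 60, n),
                orients=rng.choice([1, -1], n),
                pos5=rng.integers(1, 40, n),
                pos3=rng.integers(1, 40, n),
            )
            with_zero = site_likelihoods(site, DamageModel.flat(0.0)).loglik
            without = site_likelihoods(site, None).loglik
            assert np.allclose(with_zero, without, atol=1e-12, rtol=0)

    def test_filters_and_cap(self, std_damage_model):
        # low-mapq and low-qual reads are excluded from the effective depth
        site = PileupSite(
            chrom="1", pos=1, ref="C",
            bases=np.array(list("CCCC")),
            quals=np.array([40, 14, 40, 40]),
            mapqs=np.array([37, 37, 14, 37]),
            orients=np.ones(4, dtype=np.int64),
            pos5=np.full(4, 10, dtype=np.int64),
            pos3=np.full(4, 10, dtype=np.int64),
        )
        lik = site_likelihoods(site, std_damage_model)
        assert lik.effective_depth == 2
        # a quality-93 base behaves exactly like quality 40 (cap)
        s93 = make_site("C", quals=93)
        s40 = make_site("C", quals=40)
        assert np.allclose(
            site_likelihoods(s93, None).loglik, site_likelihoods(s40, None).loglik
        )

    def test_zero_retained_reads(self):
        site = make_site("CCC", quals=5)
        lik = site_likelihoods(site, None)
        assert lik.effective_depth == 0
        assert np.all(lik.loglik == 0.0)


class TestCallSite:
    def lik(self, ll, depth=10):
        return GenotypeLikelihoods("1", 1, "C", np.array(ll, dtype=float), depth)

    def test_low_depth_missing(self):
        ll = np.zeros(10)
        ll[gt_index("C", "C")] = 10.0
        call = call_site(self.lik(ll, depth=6))
        assert call.genotype is None
        assert "low-depth" in call.filters

    def test_depth_boundary_inclusive(self):
        ll = np.zeros(10)
        ll[gt_index("C", "C")] = 10.0
        assert call_site(self.lik(ll, depth=7)).genotype == ("C", "C")

    def test_het_demotion_below_gq30(self):
        ll = np.full(10, -50.0)
        ln10 = np.log(10)
        ll[gt_index("C", "T")] = 0.0
        ll[gt_index("C", "C")] = -2.9 * ln10  # GQ 29 to the het
        ll[gt_index("T", "T")] = -8.0 * ln10
        call = call_site(self.lik(ll))
        assert call.genotype == ("C", "C")
        assert "het-demoted" in call.filters
        # GQ recomputed against the next-best homozygote
        assert call.gq == pytest.approx((8.0 - 2.9) * 10, abs=1e-6)

    def test_het_kept_at_gq30(self):
        ll = np.full(10, -50.0)
        ln10 = np.log(10)
        ll[gt_index("C", "T")] = 0.0
        ll[gt_index("C", "C")] = -3.0 * ln10  # GQ exactly 30
        call = call_site(self.lik(ll))
        assert call.genotype == ("C", "T")
        assert call.filters == []
        assert call.gq == pytest.approx(30.0, abs=1e-9)

    def test_demoted_genotype_has_support(self, std_damage_model):
        # demotion must never return a genotype with zero likelihood support
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(7, 20))
            site = PileupSite(
                chrom="1", pos=1, ref="C",
                bases=rng.choice(list("ACGT"), n, p=[0.1, 0.45, 0.1, 0.35]),
                quals=rng.integers(15, 45, n),
                mapqs=np.full(n, 37),
                orients=rng.choice([1, -1], n),
                pos5=rng.integers(1, 30, n),
                pos3=rng.integers(1, 30, n),
            )
            lik = site_likelihoods(site, std_damage_model)
            call = call_site(lik)
            if call.genotype is not None:
                assert np.isfinite(lik.loglik[GENOTYPES.index(call.genotype)])
                assert call.gq >= 0

    def test_tie_break_deterministic(self):
        call = call_site(self.lik(np.zeros(10)))
        assert call.genotype == GENOTYPES[0]
        assert call.gq == 0.0


class TestRegionVcf:
    def test_empty_stream(self):
        buf = io.StringIO()
        write_vcf(call_region([], None), buf)
        lines = buf.getvalue().splitlines()
        assert lines[-1].startswith("#CHROM")
        assert all(l.startswith("#") for l in lines)

    def test_deterministic_output(self, small_truth_panel, std_damage_model):
        reads = simdata.simulate_reads(small_truth_panel, 9.0, std_damage_model, seed=4)
        sites = [
            PileupSite(s.chrom, s.pos, s.ref, s.bases, s.quals, s.mapqs,
                       s.orients, s.pos5, s.pos3)
            for s in reads
        ]
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_vcf(call_region(sites, std_damage_model), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_concordance_on_simulated_truth(self, single_pop_config, std_damage_model):
        panel = simdata.simulate_genotypes(single_pop_config, 3000, seed=77)
        reads = simdata.simulate_reads(panel, 9.0, std_damage_model, qual_profile=30, seed=78)
        sites = [
            PileupSite(s.chrom, s.pos, s.ref, s.bases, s.quals, s.mapqs,
                       s.orients, s.pos5, s.pos3)
            for s in reads
        ]
        calls = call_region(sites, std_damage_model)
        ok = tot = 0
        for call, stack in zip(calls, reads):
            if call.genotype is None:
                continue
            tot += 1
            ok += call.genotype == tuple(sorted(stack.true_genotype))
        assert tot > 2000
        assert ok / tot > 0.99

    def test_vcf_readable_by_cyvcf2(self, tmp_path, small_truth_panel, std_damage_model):
        cyvcf2 = pytest.importorskip("cyvcf2")
        reads = simdata.simulate_reads(small_truth_panel, 9.0, std_damage_model, seed=5)
        sites = [
            PileupSite(s.chrom, s.pos, s.ref, s.bases, s.quals, s.mapqs,
                       s.orients, s.pos5, s.pos3)
            for s in reads
        ]
        calls = call_region(sites, std_damage_model)
        path = tmp_path / "calls.vcf"
        with open(path, "w") as fh:
            write_vcf(calls, fh)
        records = list(cyvcf2.VCF(str(path)))
        assert len(records) == len(calls)
        called = [c for c in calls if c.genotype is not None]
        passed = [r for r in records if r.FILTER is None]
        assert len(passed) == len(called)


class TestPileupIO:
    def test_dialect_roundtrip(self, small_truth_panel, std_damage_model, tmp_path):
        reads = simdata.simulate_reads(small_truth_panel, 6.0, std_damage_model, seed=6)
        path = tmp_path / "stack.pileup"
        reads.to_pileup(path)
        with open(path) as fh:
            sites = list(read_pileup(fh))
        assert len(sites) == len(reads)
        for orig, back in zip(reads, sites):
            assert back.pos == orig.pos
            assert back.ref == orig.ref
            assert np.array_equal(back.bases, orig.bases)
            assert np.array_equal(back.quals, orig.quals)
            assert np.array_equal(back.orients, orig.orients)
            assert np.array_equal(back.pos5, orig.pos5)
            assert np.array_equal(back.pos3, orig.pos3)

    def test_parse_error_reports_line(self):
        with pytest.raises(PileupParseError, match="line 2"):
            list(read_pileup(["1\t10\tC\tC:30:37:+:1:70", "1\tbad\tC\t"]))

    def test_samtools_basic_columns(self):
        line = "chr1\t50\tc\t5\t.,.Tt\tIIIII"
        site = next(read_pileup([line]))
        assert site.ref == "C"
        assert list(site.bases) == ["C", "C", "C", "T", "T"]
        assert list(site.orients) == [1, -1, 1, 1, -1]
        assert np.all(site.quals == 40)
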