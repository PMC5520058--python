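"""End-to-end synthetic study: simulate, fit damage, call, date, CNV, loci.

`run_synthetic_study` wires every module together on a simulated
four-population dog world (ancient sample + European, Indian, Asian village
dogs, outgroup-polarized): reads with deamination damage are tabulated and
fitted, genotypes called damage-aware, f-statistics and an f4-ratio admixture
proportion estimated, the ancient-European divergence dated from the
exclusive derived-allele-sharing ratio and calibrated to years, copy number
recovered at a synthetic amylase-like locus, and candidate loci classified.
The machine-readable report carries all estimates, intervals, seeds and
pass/fail flags against the configured truths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import cnvdepth, damagefit, damcall, dating, fstats, loci_trees, simdata

__all__ = ["RunConfig", "run_synthetic_study"]

log = logging.getLogger("paleodog")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Parameters of the synthetic study; every stage derives its own seed."""

    seed: int = 1
    # damage / calling stage
    damage_a: float = 0.3
    damage_b: float = 0.3
    damage_c: float = 1.0
    coverage: float = 9.0
    n_call_sites: int = 2000
    n_damage_sites: int = 20_000
    # dating stage
    coal: dating.CoalParams = field(
        default_factory=lambda: dating.CoalParams(
            theta1=1e-4, theta2=1e-4, p0=1e-5, p2=2e-5, p3=3e-5, alpha=0.2,
            tau1=1.5e-5,
        )
    )
    n_dating_sites: int = 200_000
    sample_age_years: float = 7000.0
    generation_years: float = 3.0
    mu: float = 4e-9
    # f-statistics stage
    admixture_alpha: float = 0.3
    n_fstat_sites: int = 60_000
    # CNV stage
    base_depth: float = 9.0
    cn_true: tuple[int, ...] = (2, 3, 8)
    # loci stage
    n_locus_windows: int = 30

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_synthetic_study(config: RunConfig) -> dict:
    """Run the whole chain; returns the versioned JSON-serializable report."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t_start = time.time()

    def stage(name):
        log.info("stage %s (seed %d)", name, _stage_seed(config.seed, name))
        return _stage_seed(config.seed, name)

    # ------------------------------------------------------------------ damage
    try:
        seed = stage("damage")
        truth_model = damagefit.DamageModel.flat(
            config.damage_a, config.damage_b, config.damage_c
        )
        world = simdata.DemographyConfig(
            populations=["POP"], pop_sizes={"POP": 0.01}, samples={"POP": 1}
        )
        truth_panel = simdata.simulate_genotypes(world, config.n_damage_sites, seed)
        reads = simdata.simulate_reads(
            truth_panel, config.coverage, truth_model, qual_profile=30, seed=seed + 1
        )
        t5, t3 = damagefit.tabulate_mismatches(reads)
        fit5 = damagefit.fit_weibull(t5)
        fit3 = damagefit.fit_weibull(t3)
        fitted_model = damagefit.DamageModel(five_prime=fit5, three_prime=fit3)
        report["stages"]["damage"] = {
            "true": {"a": config.damage_a, "b": config.damage_b, "c": config.damage_c},
            "fit_5p": {"a": fit5.a, "b": fit5.b, "c": fit5.c},
            "fit_3p": {"a": fit3.a, "b": fit3.b, "c": fit3.c},
            "amplitude_ok": bool(abs(fit5.a - config.damage_a) < 0.05),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage damage failed (seed {config.seed}): {e}") from e

    # ----------------------------------------------------------------- calling
    try:
        seed = stage("calling")
        pile_sites = [
            damcall.PileupSite(
                s.chrom, s.pos, s.ref, s.bases, s.quals, s.mapqs, s.orients, s.pos5, s.pos3
            )
            for s in reads[: config.n_call_sites]
        ]
        reads = reads[: config.n_call_sites]
        calls_aware = damcall.call_region(pile_sites, fitted_model)
        calls_naive = damcall.call_region(pile_sites, None)
        truth_gt = [s.true_genotype for s in reads]

        def concordance(calls):
            ok = tot = 0
            for c, gt in zip(calls, truth_gt):
                if c.genotype is None:
                    continue
                tot += 1
                ok += tuple(sorted(c.genotype)) == tuple(sorted(gt))
            return ok / tot if tot else np.nan, tot

        def false_het(calls):
            fh = n = 0
            for c, gt in zip(calls, truth_gt):
                if c.genotype is None or gt[0] != gt[1]:
                    continue
                n += 1
                fh += c.genotype[0] != c.genotype[1]
            return fh, n

        conc, n_called = concordance(calls_aware)
        fh_aware, n_hom = false_het(calls_aware)
        fh_naive, _ = false_het(calls_naive)
        report["stages"]["calling"] = {
            "concordance": conc,
            "n_called": n_called,
            "false_het_damage_aware": fh_aware,
            "false_het_naive": fh_naive,
            "n_hom_truth": n_hom,
            "damage_aware_reduces_false_het": bool(fh_aware <= fh_naive),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage calling failed (seed {config.seed}): {e}") from e

    # ----------------------------------------------------------------- fstats
    try:
        seed = stage("fstats")
        alpha = config.admixture_alpha
        # (((A,(B,X)),C),OUT) with X receiving alpha from C:
        # f4(A,OUT;X,C)/f4(A,OUT;B,C) = 1 - alpha exactly
        world = simdata.DemographyConfig(
            populations=["OUT", "A", "B", "X", "C"],
            pop_sizes={p: 0.002 for p in ["OUT", "A", "B", "X", "C", "N1", "N2", "N3", "ROOT"]},
            splits=[
                (0.010, ["B", "X"], "N1"),
                (0.016, ["A", "N1"], "N2"),
                (0.024, ["N2", "C"], "N3"),
                (0.060, ["N3", "OUT"], "ROOT"),
            ],
            admixture_edges=[("C", "X", 0.002, alpha)],
            samples={"OUT": 2, "A": 4, "B": 4, "X": 4, "C": 4},
        )
        panel = simdata.simulate_genotypes(world, config.n_fstat_sites, seed,
                                           n_chromosomes=20, block_size=10**9)
        fp = fstats.FreqPanel.from_genotype_panel(panel)
        f3_res = fstats.f3(fp, "OUT", "B", "X")
        d_res = fstats.d_stat(fp, "B", "X", "C", "OUT")
        ratio = fstats.f4_ratio(
            fp, numerator=("A", "OUT", "X", "C"), denominator=("A", "OUT", "B", "C")
        )
        alpha_hat = 1.0 - ratio.estimate
        report["stages"]["fstats"] = {
            "outgroup_f3": dataclasses.asdict(f3_res),
            "d_stat": dataclasses.asdict(d_res),
            "f4_ratio": dataclasses.asdict(ratio),
            "admixture_alpha_true": alpha,
            "admixture_alpha_hat": float(alpha_hat),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage fstats failed (seed {config.seed}): {e}") from e

    # ------------------------------------------------------------------ dating
    try:
        seed = stage("dating")
        coal = config.coal
        panel = dating.simulate_dating_panel(coal, config.n_dating_sites, seed)
        hap = dating.haploidize(panel, list(dating.DATING_POPS), seed + 1)
        counts = dating.count_sharing_patterns(hap)
        ratio_est = dating.sharing_ratio(counts)
        tau1_est = dating.solve_tau1(ratio_est, coal)
        calib = dating.calibrate(
            tau1_est, config.sample_age_years, config.mu, config.generation_years
        )
        identity_age = dating.calibrate_time(
            tau1_est.tau1,
            dating.mu_upper(tau1_est.tau1, config.sample_age_years, config.generation_years),
            config.generation_years,
        )
        in_ci = (
            tau1_est.ci_low is not None
            and tau1_est.ci_low <= coal.tau1 <= tau1_est.ci_high
        )
        report["stages"]["dating"] = {
            "true_tau1": coal.tau1,
            "ratio": dataclasses.asdict(ratio_est),
            "tau1": dataclasses.asdict(tau1_est),
            "mu_upper": calib.mu_upper,
            "years": calib.years,
            "years_ci": calib.years_ci,
            "tau1_in_ci": bool(in_ci),
            "calibration_identity_ok": bool(
                abs(identity_age - config.sample_age_years) < 1e-6
            ),
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage dating failed (seed {config.seed}): {e}") from e

    # -------------------------------------------------------------------- cnv
    try:
        seed = stage("cnv")
        w = cnvdepth.WINDOW_SIZE
        n_windows = 400
        rng = np.random.default_rng(seed)
        gc = np.clip(rng.normal(0.45, 0.08, n_windows), 0.2, 0.8)
        locus_results = {}
        for k, cn in enumerate(config.cn_true):
            # one CN segment per simulated genome, away from the control head
            seg = ((250 * w, 280 * w), cn)
            track = simdata.simulate_depth(
                [seg], gc, simdata.ushaped_bias(0.5), config.base_depth, seed + k, window_size=w
            )
            control = [("1", 0, 200 * w)]
            corrected, curve = cnvdepth.gc_correct(track, control)
            cn_track = cnvdepth.window_copy_number(corrected, curve.control_mean)
            point, call = cnvdepth.locus_copy_number(cn_track, ("1", 255 * w, 275 * w))
            locus_results[str(cn)] = {"point": point, "call": call, "ok": call == cn}
        report["stages"]["cnv"] = locus_results
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage cnv failed (seed {config.seed}): {e}") from e

    # ------------------------------------------------------------------- loci
    try:
        seed = stage("loci")
        # more dogs than wolves so fixed dog/wolf differences have MAF < 0.5
        # and survive the minor-allele-frequency filter, as in real panels
        world = simdata.DemographyConfig(
            populations=["DOG", "WOLF"],
            pop_sizes={"DOG": 0.002, "WOLF": 0.002, "ROOT": 0.002},
            splits=[(0.02, ["DOG", "WOLF"], "ROOT")],
            samples={"DOG": 8, "WOLF": 4},
        )
        n_win = config.n_locus_windows
        win_sites = 120
        panel = simdata.simulate_genotypes(
            world, n_win * win_sites, seed, variable_only=True
        )
        clean_panel = panel
        # graft an F1 query: one dog allele + one wolf allele at every site
        n_dog = sum(p == "DOG" for p in panel.sample_pops)
        dog_hap = (panel.genotypes[:, 0] >= 1).astype(np.int8)
        wolf_hap = (panel.genotypes[:, n_dog] >= 1).astype(np.int8)
        f1 = dog_hap + wolf_hap
        G = np.column_stack([panel.genotypes, f1])
        panel = simdata.GenotypePanel(
            chrom=panel.chrom, pos=panel.pos, block_id=panel.block_id,
            samples=panel.samples + ["F1"],
            sample_pops=panel.sample_pops + ["QUERY"],
            genotypes=G, polarized=True,
        )
        windows = [np.arange(i * win_sites, (i + 1) * win_sites) for i in range(n_win)]
        calls = loci_trees.classify_locus(
            panel, windows,
            dog_samples=[s for s, p in zip(panel.samples, panel.sample_pops) if p == "DOG"],
            wolf_samples=[s for s, p in zip(panel.samples, panel.sample_pops) if p == "WOLF"],
            query="F1",
        )
        classified = [c for c in calls if c.label != "unclassified"]
        het_frac = (
            sum(c.label == "heterozygous-like" for c in classified) / len(classified)
            if classified else np.nan
        )
        tree, support = loci_trees.window_bootstrap_support(
            clean_panel.take_sites(np.arange(min(4000, clean_panel.n_sites))),
            loci_trees.GeneticMap.uniform(clean_panel.n_sites + 1, 0.05),
            n_replicates=50, seed=seed,
        )
        clade = frozenset(
            s for s, p in zip(clean_panel.samples, clean_panel.sample_pops) if p == "WOLF"
        )
        clade_support = support.get(clade)
        report["stages"]["loci"] = {
            "f1_heterozygous_like_fraction": het_frac,
            "n_windows_classified": len(classified),
            "wolf_clade_support": clade_support,
        }
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage loci failed (seed {config.seed}): {e}") from e

    report["runtime_seconds"] = round(time.time() - t_start, 2)
    report["passed"] = all([
        report["stages"]["damage"]["amplitude_ok"],
        report["stages"]["calling"]["damage_aware_reduces_false_het"],
        report["stages"]["dating"]["calibration_identity_ok"],
        all(v["ok"] for v in report["stages"]["cnv"].values()),
    ])
    return report
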