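"""Synthetic inputs for the ancient-dog analysis chain.

Everything downstream (damage fitting, damage-aware calling, f-statistics,
divergence dating, copy-number estimation, trees) consumes data produced here:
coalescent genotype panels under a user-specified split/admixture demography,
read stacks carrying position-dependent post-mortem damage, and per-position
depth tracks with known integer copy number and GC bias.

All demographic quantities are mutation-scaled: divergence times are expected
mutations per site, population sizes are theta = 4*N*mu, and a pair of lineages
in a population of size theta coalesces at rate 2/theta.  Conversion to years
happens only in :mod:`paleodog.dating`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import msprime
import numpy as np

__all__ = [
    "DemographyConfig",
    "GenotypePanel",
    "ReadStackSite",
    "SimulatedReadStack",
    "DepthTrack",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_depth",
    "flat_bias",
    "ushaped_bias",
]

BASES = np.array(["A", "C", "G", "T"])
MISSING = -1

# default recombination rate between adjacent simulated sites; high enough that
# site genealogies are close to independent while keeping simulation tractable
DEFAULT_RECOMB_RATE = 2.0
DEFAULT_BLOCK_SIZE = 500


class ConfigurationError(ValueError):
    """Raised for demographies or segment sets that violate their invariants."""


# ---------------------------------------------------------------------------
# demography configuration
# ---------------------------------------------------------------------------

@dataclass
class DemographyConfig:
    """Piecewise-constant-size split/admixture demography, mutation-scaled.

    Parameters
    ----------
    populations:
        Leaf population labels (sampled populations).
    pop_sizes:
        theta = 4*N*mu per branch label (leaves and internal nodes).
    splits:
        ``(time, [derived labels], ancestral label)`` tuples, time in expected
        mutations per site, ordered or unordered (validated topologically).
    admixture_edges:
        ``(source, dest, time, proportion)``: forward in time, ``dest``
        receives ``proportion`` of its ancestry from ``source`` at ``time``.
    samples:
        Diploid individuals to sample per leaf population (default 1 each).
    sample_ages:
        Sampling time (mutation units before present) per population,
        default 0.
    ascertainment:
        Label of the population in which panel sites must be variable, or
        ``"none"``.
    """

    populations: list[str]
    pop_sizes: dict[str, float]
    splits: list[tuple[float, list[str], str]] = field(default_factory=list)
    admixture_edges: list[tuple[str, str, float, float]] = field(default_factory=list)
    samples: dict[str, int] = field(default_factory=dict)
    sample_ages: dict[str, float] = field(default_factory=dict)
    ascertainment: str = "none"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        labels = set(self.populations)
        for t, derived, anc in self.splits:
            if t <= 0:
                raise ConfigurationError(f"split time must be > 0, got {t}")
            labels.add(anc)
        for lab, th in self.pop_sizes.items():
            if th < 0:
                raise ConfigurationError(f"theta for {lab} must be >= 0")
        # topological ordering: the split merging a label must be younger than
        # the split merging its ancestral label
        merge_time: dict[str, float] = {}
        for t, derived, anc in self.splits:
            for d in derived:
                if d in merge_time:
                    raise ConfigurationError(f"population {d} merged twice")
                merge_time[d] = t
        for t, derived, anc in self.splits:
            if anc in merge_time and merge_time[anc] < t:
                raise ConfigurationError(
                    f"split of {anc} at {merge_time[anc]} predates child split at {t}"
                )
        for src, dst, t, p in self.admixture_edges:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"admixture proportion {p} outside [0,1]")
            if t < 0:
                raise ConfigurationError("admixture time must be >= 0")
        for pop, age in self.sample_ages.items():
            first = merge_time.get(pop, np.inf)
            if age >= first:
                raise ConfigurationError(
                    f"sample age {age} for {pop} is not below its first split {first}"
                )
        if self.ascertainment != "none" and self.ascertainment not in self.populations:
            raise ConfigurationError(
                f"ascertainment panel {self.ascertainment!r} is not a sampled population"
            )

    # -- (de)serialization --------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "populations": self.populations,
            "pop_sizes": self.pop_sizes,
            "splits": [[t, d, a] for t, d, a in self.splits],
            "admixture_edges": [list(e) for e in self.admixture_edges],
            "samples": self.samples,
            "sample_ages": self.sample_ages,
            "ascertainment": self.ascertainment,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DemographyConfig":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            populations=obj["populations"],
            pop_sizes={k: float(v) for k, v in obj["pop_sizes"].items()},
            splits=[(float(t), list(d), a) for t, d, a in obj["splits"]],
            admixture_edges=[
                (s, d, float(t), float(p)) for s, d, t, p in obj.get("admixture_edges", [])
            ],
            samples={k: int(v) for k, v in obj.get("samples", {}).items()},
            sample_ages={k: float(v) for k, v in obj.get("sample_ages", {}).items()},
            ascertainment=obj.get("ascertainment", "none"),
        )

    # -- msprime adapter ----------------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        """Translate to an msprime Demography with mutation-scaled time.

        theta = 4*N*mu with mu := 1 per site per generation, so N = theta/4
        and a lineage pair coalesces at rate 1/(2N) = 2/theta.
        """
        dem = msprime.Demography()
        labels = list(self.populations)
        for t, derived, anc in sorted(self.splits, key=lambda s: s[0]):
            if anc not in labels:
                labels.append(anc)
        for lab in labels:
            theta = self.pop_sizes.get(lab)
            if theta is None:
                raise ConfigurationError(f"no theta given for population {lab}")
            dem.add_population(name=lab, initial_size=max(theta, 1e-300) / 4.0)
        # admixture pulses must be registered before older splits fire
        for src, dst, t, p in sorted(self.admixture_edges, key=lambda e: e[2]):
            dem.add_mass_migration(time=t, source=dst, dest=src, proportion=p)
        for t, derived, anc in sorted(self.splits, key=lambda s: s[0]):
            dem.add_population_split(time=t, derived=list(derived), ancestral=anc)
        dem.sort_events()
        return dem


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Polarized multi-sample genotype matrix with jackknife block labels.

    ``genotypes`` holds the diploid derived-allele dosage in {0, 1, 2} with
    ``-1`` for missing, one row per site and one column per sample.  The
    derived state is defined against the outgroup/ancestral allele
    (``polarized=True`` for everything produced by the simulator).
    """

    chrom: np.ndarray
    pos: np.ndarray
    block_id: np.ndarray
    samples: list[str]
    sample_pops: list[str]
    genotypes: np.ndarray
    polarized: bool = True
    ascertainment: str = "none"
    ancestral_allele: np.ndarray | None = None
    derived_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_sites = len(self.pos)
        if self.genotypes.shape != (n_sites, len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites x samples")
        g = self.genotypes
        ok = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.sample_pops) if p == pop])

    def variable_in(self, pop: str) -> np.ndarray:
        """Boolean mask of sites segregating within population ``pop``."""
        idx = self.pop_indices(pop)
        sub = self.genotypes[:, idx]
        valid = sub != MISSING
        any_der = ((sub > 0) & valid).any(axis=1)
        any_anc = ((sub < 2) & valid).any(axis=1)
        return any_der & any_anc

    def take_sites(self, mask_or_idx) -> "GenotypePanel":
        return GenotypePanel(
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            block_id=self.block_id[mask_or_idx],
            samples=list(self.samples),
            sample_pops=list(self.sample_pops),
            genotypes=self.genotypes[mask_or_idx],
            polarized=self.polarized,
            ascertainment=self.ascertainment,
            ancestral_allele=None if self.ancestral_allele is None else self.ancestral_allele[mask_or_idx],
            derived_allele=None if self.derived_allele is None else self.derived_allele[mask_or_idx],
        )

    # -- TSV round trip -----------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#polarized=%s\tascertainment=%s\n" % (self.polarized, self.ascertainment))
            fh.write("#pops=%s\n" % ",".join(self.sample_pops))
            fh.write("chrom\tpos\tblock\t" + "\t".join(self.samples) + "\n")
            for i in range(self.n_sites):
                row = "\t".join(str(int(d)) for d in self.genotypes[i])
                fh.write(f"{self.chrom[i]}\t{self.pos[i]}\t{self.block_id[i]}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        with open(path) as fh:
            meta = fh.readline().strip().lstrip("#").split("\t")
            polarized = meta[0].split("=")[1] == "True"
            ascert = meta[1].split("=")[1]
            pops = fh.readline().strip().lstrip("#").split("=", 1)[1].split(",")
            header = fh.readline().rstrip("\n").split("\t")
            samples = header[3:]
            chroms, poss, blocks, rows = [], [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                chroms.append(parts[0])
                poss.append(int(parts[1]))
                blocks.append(int(parts[2]))
                rows.append([int(x) for x in parts[3:]])
        return cls(
            chrom=np.array(chroms),
            pos=np.array(poss, dtype=np.int64),
            block_id=np.array(blocks, dtype=np.int64),
            samples=samples,
            sample_pops=pops,
            genotypes=np.array(rows, dtype=np.int8),
            polarized=polarized,
            ascertainment=ascert,
        )

    # -- EIGENSTRAT-like triple --------------------------------------------
    def to_eigenstrat(self, prefix: str) -> None:
        """Write <prefix>.geno/.snp/.ind (dosage coded, 9 = missing)."""
        with open(prefix + ".ind", "w") as fh:
            for s, p in zip(self.samples, self.sample_pops):
                fh.write(f"{s}\tU\t{p}\n")
        anc = self.ancestral_allele
        der = self.derived_allele
        with open(prefix + ".snp", "w") as fh:
            for i in range(self.n_sites):
                a = anc[i] if anc is not None else "A"
                d = der[i] if der is not None else "C"
                fh.write(
                    f"snp{i}\t{self.chrom[i]}\t0.0\t{self.pos[i]}\t{d}\t{a}\n"
                )
        with open(prefix + ".geno", "w") as fh:
            for i in range(self.n_sites):
                fh.write(
                    "".join(
                        "9" if g == MISSING else str(int(g)) for g in self.genotypes[i]
                    )
                    + "\n"
                )

    @classmethod
    def from_eigenstrat(cls, prefix: str, block_size: int = DEFAULT_BLOCK_SIZE) -> "GenotypePanel":
        samples, pops = [], []
        with open(prefix + ".ind") as fh:
            for line in fh:
                parts = line.split()
                samples.append(parts[0])
                pops.append(parts[2])
        chroms, poss, ders, ancs = [], [], [], []
        with open(prefix + ".snp") as fh:
            for line in fh:
                parts = line.split()
                chroms.append(parts[1])
                poss.append(int(parts[3]))
                ders.append(parts[4])
                ancs.append(parts[5])
        rows = []
        with open(prefix + ".geno") as fh:
            for line in fh:
                rows.append([MISSING if c == "9" else int(c) for c in line.strip()])
        n = len(poss)
        return cls(
            chrom=np.array(chroms),
            pos=np.array(poss, dtype=np.int64),
            block_id=np.arange(n) // block_size,
            samples=samples,
            sample_pops=pops,
            genotypes=np.array(rows, dtype=np.int8),
            polarized=True,
            ancestral_allele=np.array(ancs),
            derived_allele=np.array(ders),
        )


# ---------------------------------------------------------------------------
# genotype simulation (msprime adapter)
# ---------------------------------------------------------------------------

def _assign_alleles(n_sites: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    anc = BASES[rng.integers(0, 4, size=n_sites)]
    shift = rng.integers(1, 4, size=n_sites)
    der = BASES[(np.searchsorted(BASES, anc) + shift) % 4]
    return anc, der


def simulate_genotypes(
    config: DemographyConfig,
    n_sites: int,
    seed: int,
    *,
    variable_only: bool = False,
    recombination_rate: float = DEFAULT_RECOMB_RATE,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_chromosomes: int = 1,
) -> GenotypePanel:
    """Draw a polarized genotype panel from the coalescent.

    One simulated base pair corresponds to one panel site; mutations are
    Poisson on branches with rate 1 (mutation-scaled time), so monomorphic
    sites are retained unless ``variable_only`` or ascertainment is requested.
    Ascertainment (``config.ascertainment``) keeps only sites variable within
    the designated panel, by rejection, until ``n_sites`` sites accumulate.
    Deterministic given ``seed``.

    ``n_chromosomes`` splits the panel into independently simulated
    chromosomes.  Within one simulated sequence, deep genealogy is correlated
    over long ranges even under free-ish recombination, so jackknife blocks
    (which never span chromosomes) only have honest coverage when the
    between-block independence is real — use several chromosomes whenever
    block-level standard errors matter.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_chromosomes > 1:
        rng = np.random.default_rng(seed)
        per = np.full(n_chromosomes, n_sites // n_chromosomes, dtype=int)
        per[: n_sites % n_chromosomes] += 1
        parts = []
        block_offset = 0
        for ci, k in enumerate(per[per > 0]):
            sub = simulate_genotypes(
                config, int(k), int(rng.integers(1, 2**31 - 1)),
                variable_only=variable_only,
                recombination_rate=recombination_rate,
                block_size=block_size,
            )
            sub.chrom = np.repeat(str(ci + 1), sub.n_sites)
            sub.block_id = sub.block_id + block_offset
            block_offset = int(sub.block_id.max()) + 1
            parts.append(sub)
        return GenotypePanel(
            chrom=np.concatenate([p.chrom for p in parts]),
            pos=np.concatenate([p.pos for p in parts]),
            block_id=np.concatenate([p.block_id for p in parts]),
            samples=parts[0].samples,
            sample_pops=parts[0].sample_pops,
            genotypes=np.vstack([p.genotypes for p in parts]),
            polarized=True,
            ascertainment=config.ascertainment,
            ancestral_allele=np.concatenate([p.ancestral_allele for p in parts]),
            derived_allele=np.concatenate([p.derived_allele for p in parts]),
        )
    config.validate()
    rng = np.random.default_rng(seed)
    dem = config.to_msprime()
    sample_sets = []
    sample_names: list[str] = []
    sample_pops: list[str] = []
    for pop in config.populations:
        k = config.samples.get(pop, 1)
        age = config.sample_ages.get(pop, 0.0)
        sample_sets.append(msprime.SampleSet(k, population=pop, time=age, ploidy=2))
        for j in range(k):
            sample_names.append(f"{pop}_{j}")
            sample_pops.append(pop)

    ascertain = config.ascertainment != "none"
    need_filter = variable_only or ascertain

    collected: list[np.ndarray] = []
    total = 0
    # chunk length: for the all-sites panel one chunk of exactly n_sites bp;
    # under rejection, grow chunks adaptively
    chunk = n_sites
    guard = 0
    panels = []
    while total < n_sites:
        guard += 1
        if guard > 50:
            raise ConfigurationError(
                "ascertainment rejection did not accumulate enough variable sites"
            )
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=dem,
            sequence_length=chunk,
            recombination_rate=recombination_rate,
            discrete_genome=True,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=1.0,
            model=msprime.BinaryMutationModel(),
            random_seed=int(rng.integers(1, 2**31 - 1)),
            discrete_genome=True,
        )
        H = mts.genotype_matrix()  # (variants, haplotypes), 0 = ancestral
        H = np.minimum(H, 1)
        dos = (H[:, 0::2] + H[:, 1::2]).astype(np.int8)
        var_pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
        n_mut = np.array([len(s.mutations) for s in mts.sites()], dtype=np.int64)
        # infinite-sites emulation: discard positions hit by more than one
        # mutation (incl. two discrete-genome sites at the same bp)
        if len(var_pos):
            uniq = np.r_[True, np.diff(var_pos) > 0] & np.r_[var_pos[1:] != var_pos[:-1], True]
            keep = uniq & (n_mut == 1)
            dos, var_pos = dos[keep], var_pos[keep]
        if need_filter:
            panel_rows = dos
            mask = np.ones(len(var_pos), dtype=bool)
            if variable_only or ascertain:
                if ascertain:
                    idx = [i for i, p in enumerate(sample_pops) if p == config.ascertainment]
                else:
                    idx = list(range(len(sample_pops)))
                sub = panel_rows[:, idx]
                mask &= (sub > 0).any(axis=1) & (sub < 2).any(axis=1)
            panel_rows = panel_rows[mask]
            panels.append(panel_rows)
            total += len(panel_rows)
            # adapt chunk size based on observed yield
            if total < n_sites:
                rate = max(total, 1) / (guard * chunk)
                chunk = int(min(max((n_sites - total) / max(rate, 1e-9) * 1.3, 1000), 5e6))
        else:
            full = np.zeros((chunk, len(sample_names)), dtype=np.int8)
            full[var_pos] = dos
            panels.append(full)
            total += chunk

    G = np.vstack(panels)[:n_sites]
    n = len(G)
    anc, der = _assign_alleles(n, rng)
    return GenotypePanel(
        chrom=np.repeat("1", n),
        pos=np.arange(1, n + 1, dtype=np.int64),
        block_id=np.arange(n, dtype=np.int64) // block_size,
        samples=sample_names,
        sample_pops=sample_pops,
        genotypes=G,
        polarized=True,
        ascertainment=config.ascertainment,
        ancestral_allele=anc,
        derived_allele=der,
    )


# ---------------------------------------------------------------------------
# read simulation with post-mortem damage
# ---------------------------------------------------------------------------

@dataclass
class ReadStackSite:
    """Simulated read stack over one site (reference = ancestral allele)."""

    chrom: str
    pos: int
    ref: str
    true_genotype: tuple[str, str]
    bases: np.ndarray
    quals: np.ndarray
    mapqs: np.ndarray
    orients: np.ndarray  # +1 forward, -1 reverse
    pos5: np.ndarray
    pos3: np.ndarray
    lengths: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.bases)


class SimulatedReadStack(list):
    """A list of :class:`ReadStackSite`, writable as the pileup dialect."""

    def to_pileup(self, path) -> None:
        with open(path, "w") as fh:
            for site in self:
                reads = " ".join(
                    f"{site.bases[i]}:{int(site.quals[i])}:{int(site.mapqs[i])}:"
                    f"{'+' if site.orients[i] > 0 else '-'}:{int(site.pos5[i])}:{int(site.pos3[i])}"
                    for i in range(site.depth)
                )
                fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{reads}\n")


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _apply_damage_vector(
    bases: np.ndarray,
    orients: np.ndarray,
    pos5: np.ndarray,
    pos3: np.ndarray,
    damage,
    rng: np.random.Generator,
) -> np.ndarray:
    """C>T / G>A deamination in reference-forward coordinates.

    Forward reads deaminate reference C at their 5' end and reference G at
    their 3' end; reverse reads show the complementary pattern (their own 5'
    C>T presents as G>A in reference-forward space).
    """
    if damage is None:
        return bases
    out = bases.copy()
    d5 = damage.five_prime.probability
    d3 = damage.three_prime.probability
    fwd = orients > 0
    u = rng.random(len(bases))
    # forward: C -> T with d5(pos5); G -> A with d3(pos3)
    c_fwd = fwd & (bases == "C")
    out[c_fwd & (u < d5(pos5))] = "T"
    g_fwd = fwd & (bases == "G")
    out[g_fwd & (u < d3(pos3))] = "A"
    # reverse: G -> A with d5(pos5); C -> T with d3(pos3)
    g_rev = ~fwd & (bases == "G")
    out[g_rev & (u < d5(pos5))] = "A"
    c_rev = ~fwd & (bases == "C")
    out[c_rev & (u < d3(pos3))] = "T"
    return out


def _draw_quals(qual_profile, size: int, rng: np.random.Generator) -> np.ndarray:
    if qual_profile is None:
        return np.full(size, 30, dtype=np.int64)
    if np.isscalar(qual_profile):
        return np.full(size, int(qual_profile), dtype=np.int64)
    values, probs = qual_profile
    return rng.choice(np.asarray(values, dtype=np.int64), size=size, p=probs)


def simulate_reads(
    truth: GenotypePanel,
    coverage_mean: float,
    damage,
    qual_profile=None,
    seed: int = 0,
    *,
    length_range: tuple[int, int] = (50, 90),
    mapq: int = 37,
) -> SimulatedReadStack:
    """Simulate per-site read stacks over the truth panel's first sample.

    Coverage is Poisson(``coverage_mean``) per site; each read draws an
    orientation, a length uniform in ``length_range`` (mean ~70 bp, matching
    ancient-DNA fragment sizes of 60-70 bp), and the site's offset within the
    read; the template allele is damaged first (Weibull-decay deamination) and
    sequencing error is applied afterwards at the Phred rate.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be > 0")
    rng = np.random.default_rng(seed)
    anc = truth.ancestral_allele
    der = truth.derived_allele
    if anc is None or der is None:
        raise ValueError("truth panel must carry ancestral/derived alleles")
    stack = SimulatedReadStack()
    lo, hi = length_range
    for i in range(truth.n_sites):
        dos = int(truth.genotypes[i, 0])
        if dos == MISSING:
            dos = 0
        a, d = anc[i], der[i]
        gt = {0: (a, a), 1: (a, d), 2: (d, d)}[dos]
        depth = rng.poisson(coverage_mean)
        lengths = rng.integers(lo, hi + 1, size=depth)
        p5 = rng.integers(1, lengths + 1)
        p3 = lengths - p5 + 1
        orients = np.where(rng.random(depth) < 0.5, 1, -1)
        template = np.array(gt)[rng.integers(0, 2, size=depth)]
        bases = _apply_damage_vector(template, orients, p5, p3, damage, rng)
        quals = _draw_quals(qual_profile, depth, rng)
        eps = 10.0 ** (-quals / 10.0)
        err = rng.random(depth) < eps
        if err.any():
            idx = np.searchsorted(BASES, bases[err])
            shift = rng.integers(1, 4, size=err.sum())
            bases = bases.copy()
            bases[err] = BASES[(idx + shift) % 4]
        stack.append(
            ReadStackSite(
                chrom=str(truth.chrom[i]),
                pos=int(truth.pos[i]),
                ref=a,
                true_genotype=gt,
                bases=bases,
                quals=quals,
                mapqs=np.full(depth, mapq, dtype=np.int64),
                orients=orients,
                pos5=p5,
                pos3=p3,
                lengths=lengths,
            )
        )
    return stack


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def flat_bias(gc: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(gc, dtype=float))


def ushaped_bias(strength: float = 0.6) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone-in-|GC-0.5| response: depressed depth at extreme GC."""

    def bias(gc: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        return 1.0 - strength * (2.0 * (gc - 0.5)) ** 2

    return bias


@dataclass
class DepthTrack:
    """Per-position read depth with per-window GC, 0-based half-open coords."""

    chrom: str
    start: int
    depth: np.ndarray
    gc: np.ndarray
    window_size: int

    @property
    def n_positions(self) -> int:
        return len(self.depth)

    def position_gc(self) -> np.ndarray:
        idx = np.arange(self.n_positions) // self.window_size
        return self.gc[np.minimum(idx, len(self.gc) - 1)]

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            d = self.depth
            # run-length encode equal consecutive depths
            change = np.r_[True, d[1:] != d[:-1]]
            starts = np.flatnonzero(change)
            ends = np.r_[starts[1:], len(d)]
            for s, e in zip(starts, ends):
                fh.write(f"{self.chrom}\t{self.start + s}\t{self.start + e}\t{d[s]:g}\n")

    @classmethod
    def from_bedgraph(cls, path, gc: np.ndarray, window_size: int) -> "DepthTrack":
        chrom = None
        segs = []
        with open(path) as fh:
            for line in fh:
                c, s, e, v = line.split()
                chrom = c
                segs.append((int(s), int(e), float(v)))
        start = segs[0][0]
        n = segs[-1][1] - start
        depth = np.zeros(n)
        for s, e, v in segs:
            depth[s - start : e - start] = v
        return cls(chrom=chrom, start=start, depth=depth, gc=gc, window_size=window_size)


def simulate_depth(
    cn_segments: Sequence[tuple[tuple[int, int], int]],
    gc_track: np.ndarray,
    bias: Callable[[np.ndarray], np.ndarray] | None,
    base_depth: float,
    seed: int,
    *,
    window_size: int = 3000,
    chrom: str = "1",
) -> DepthTrack:
    """Poisson depth with mean ``base_depth * (CN/2) * bias(GC)`` per position.

    ``cn_segments`` are ``((start, end), copy_number)`` in 0-based half-open
    coordinates over a background of CN=2; overlapping segments are rejected.
    ``gc_track`` gives GC content per ``window_size`` window.
    """
    gc_track = np.asarray(gc_track, dtype=float)
    if ((gc_track < 0) | (gc_track > 1)).any():
        raise ConfigurationError("GC values must lie in [0,1]")
    n = len(gc_track) * window_size
    cn = np.full(n, 2.0)
    taken = np.zeros(n, dtype=bool)
    for (s, e), c in cn_segments:
        if c < 0:
            raise ConfigurationError("copy number must be >= 0")
        if taken[s:e].any():
            raise ConfigurationError(f"overlapping CN segment [{s},{e})")
        taken[s:e] = True
        cn[s:e] = c
    bias_fn = bias if bias is not None else flat_bias
    pos_gc = gc_track[np.arange(n) // window_size]
    lam = base_depth * (cn / 2.0) * np.clip(bias_fn(pos_gc), 0.0, None)
    rng = np.random.default_rng(seed)
    depth = rng.poisson(lam).astype(float)
    return DepthTrack(chrom=chrom, start=0, depth=depth, gc=gc_track, window_size=window_size)
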