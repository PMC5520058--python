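"""Damage-aware genotype likelihoods and calling for ancient samples.

Post-mortem deamination makes ancient reads show C>T (5') and G>A (3')
mismatches that a standard caller interprets as heterozygous sites.  The
likelihood here composes damage before sequencing error: for each retained
read the probability of the observed base given a true allele is

    P(o | g) = sum_b P_err(o | b; eps) * P_dam(b | g; end position, strand)

with eps from the (capped) Phred score and P_dam the fitted Weibull decay of
:mod:`paleodog.damagefit`.  Calling follows fixed rules: sites under 7x
effective coverage are missing; a best heterozygote with Phred genotype
quality below 30 is demoted to the best homozygote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np

from .damagefit import DamageModel

__all__ = [
    "GENOTYPES",
    "PileupSite",
    "GenotypeLikelihoods",
    "GenotypeCall",
    "site_likelihoods",
    "call_site",
    "call_region",
    "read_pileup",
    "write_vcf",
    "MIN_BASE_QUAL",
    "MIN_MAP_QUAL",
    "BASE_QUAL_CAP",
    "MIN_DEPTH",
    "MIN_HET_GQ",
]

_B = ["A", "C", "G", "T"]
#: the 10 unordered diploid genotypes in fixed (tie-breaking) order
GENOTYPES = [(_B[i], _B[j]) for i in range(4) for j in range(i, 4)]
_HET = np.array([g[0] != g[1] for g in GENOTYPES])
_BIDX = {b: i for i, b in enumerate(_B)}

MIN_BASE_QUAL = 15
MIN_MAP_QUAL = 15
BASE_QUAL_CAP = 40
MIN_DEPTH = 7
MIN_HET_GQ = 30


@dataclass
class PileupSite:
    """One site's read stack: bases with qualities, strand and end positions."""

    chrom: str
    pos: int
    ref: str
    bases: np.ndarray
    quals: np.ndarray
    mapqs: np.ndarray
    orients: np.ndarray
    pos5: np.ndarray
    pos3: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bases) and not np.isin(self.bases, list("ACGTN")).all():
            raise ValueError("bases must be in {A,C,G,T,N}")


@dataclass
class GenotypeLikelihoods:
    chrom: str
    pos: int
    ref: str
    loglik: np.ndarray  # natural-log likelihood per genotype, GENOTYPES order
    effective_depth: int


@dataclass
class GenotypeCall:
    chrom: str
    pos: int
    ref: str
    genotype: tuple[str, str] | None
    gq: float
    depth: int
    filters: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _allele_obs_probs(site: PileupSite, damage: DamageModel | None) -> np.ndarray:
    """(n_reads, 4) matrix of P(observed base | true allele) per retained read.

    Caller must have filtered reads already.  Strand handling: forward reads
    deaminate reference-forward C at 5' positions and G at 3' positions;
    reverse reads present their own 5' C>T as reference-forward G>A.
    """
    n = len(site.bases)
    quals = np.minimum(site.quals, BASE_QUAL_CAP)
    eps = 10.0 ** (-quals / 10.0)
    obs = np.array([_BIDX.get(b, -1) for b in site.bases])

    if damage is not None:
        d5 = damage.five_prime.probability(site.pos5)
        d3 = damage.three_prime.probability(site.pos3)
    else:
        d5 = d3 = np.zeros(n)
    fwd = site.orients > 0
    # per read: probability that a true C is read (pre-error) as T, and G as A
    p_ct = np.where(fwd, d5, d3)
    p_ga = np.where(fwd, d3, d5)

    out = np.empty((n, 4))
    for ai, a in enumerate(_B):
        if a == "C":
            pdam = p_ct
            damaged_to = _BIDX["T"]
        elif a == "G":
            pdam = p_ga
            damaged_to = _BIDX["A"]
        else:
            pdam = np.zeros(n)
            damaged_to = ai
        # P_err(o | b) = 1 - eps if o == b else eps/3
        p_o_given_a = np.where(obs == ai, 1.0 - eps, eps / 3.0)
        p_o_given_dam = np.where(obs == damaged_to, 1.0 - eps, eps / 3.0)
        out[:, ai] = (1.0 - pdam) * p_o_given_a + pdam * p_o_given_dam
    return out


def site_likelihoods(site: PileupSite, damage: DamageModel | None) -> GenotypeLikelihoods:
    """Log-likelihood of the 10 diploid genotypes from a damaged read stack.

    Reads with mapping quality < 15 or base quality < 15 (or N base) are
    excluded; base qualities are capped at 40 before conversion to error
    rates.  The diploid likelihood averages the two alleles per read and sums
    log terms over retained reads.  With zero retained reads all genotypes are
    equally likely and the effective depth is 0.
    """
    keep = (
        (site.mapqs >= MIN_MAP_QUAL)
        & (site.quals >= MIN_BASE_QUAL)
        & (site.bases != "N")
    )
    if not keep.any():
        return GenotypeLikelihoods(site.chrom, site.pos, site.ref, np.zeros(10), 0)
    sub = PileupSite(
        site.chrom,
        site.pos,
        site.ref,
        site.bases[keep],
        site.quals[keep],
        site.mapqs[keep],
        site.orients[keep],
        site.pos5[keep],
        site.pos3[keep],
    )
    pa = _allele_obs_probs(sub, damage)  # (reads, 4)
    ll = np.empty(10)
    for gi, (a1, a2) in enumerate(GENOTYPES):
        per_read = 0.5 * pa[:, _BIDX[a1]] + 0.5 * pa[:, _BIDX[a2]]
        ll[gi] = np.log(np.maximum(per_read, 1e-300)).sum()
    return GenotypeLikelihoods(site.chrom, site.pos, site.ref, ll, int(keep.sum()))


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

_LOG10E = np.log10(np.e)


def _phred_diff(ll_best: float, ll_next: float) -> float:
    return 10.0 * _LOG10E * (ll_best - ll_next)


def call_site(
    lik: GenotypeLikelihoods,
    *,
    min_depth: int = MIN_DEPTH,
    min_het_gq: float = MIN_HET_GQ,
) -> GenotypeCall:
    """Apply the fixed calling rules to a likelihood vector.

    Effective depth below ``min_depth`` reports the site missing.  Otherwise
    the flat-prior argmax genotype is taken with GQ equal to the Phred
    difference to the runner-up; a heterozygous argmax with GQ below
    ``min_het_gq`` is demoted to the best homozygote (annotated) with GQ
    recomputed against the next-best homozygote, so demotion never yields a
    negative GQ.
    """
    if lik.effective_depth < min_depth:
        return GenotypeCall(
            lik.chrom, lik.pos, lik.ref, None, 0.0, lik.effective_depth, ["low-depth"]
        )
    ll = lik.loglik
    order = np.lexsort((np.arange(10), -ll))  # stable: ties break by genotype order
    best = order[0]
    gq = _phred_diff(ll[best], ll[order[1]])
    filters: list[str] = []
    if _HET[best] and gq < min_het_gq:
        hom_order = [i for i in order if not _HET[i]]
        best = hom_order[0]
        gq = _phred_diff(ll[best], ll[hom_order[1]])
        filters.append("het-demoted")
    return GenotypeCall(
        lik.chrom, lik.pos, lik.ref, GENOTYPES[best], float(gq), lik.effective_depth, filters
    )


# ---------------------------------------------------------------------------
# pileup dialect I/O
# ---------------------------------------------------------------------------

class PileupParseError(ValueError):
    pass


def read_pileup(lines: Iterable[str]) -> Iterator[PileupSite]:
    """Parse the tab-separated pileup dialect.

    Columns: chrom, pos (1-based), ref, then whitespace-separated read tuples
    ``base:qual:mapq:orient:pos5:pos3``.  A four-column numeric layout is
    accepted as basic samtools-mpileup (chrom, pos, ref, depth, bases, quals):
    strand is taken from base case and, lacking per-read end positions, pos5
    and pos3 are set deep in the read (position 30) so no damage adjustment
    applies — a documented conversion caveat.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PileupParseError(f"line {lineno}: expected >= 3 columns")
        chrom, pos_s, ref = parts[0], parts[1], parts[2].upper()
        try:
            pos = int(pos_s)
        except ValueError as e:
            raise PileupParseError(f"line {lineno}: bad position {pos_s!r}") from e
        if len(parts) >= 6 and parts[3].isdigit():
            # samtools-mpileup basic columns
            bases_str, quals_str = parts[4], parts[5]
            bases, quals, orients = [], [], []
            i = 0
            while i < len(bases_str):
                ch = bases_str[i]
                if ch == "^":
                    i += 2
                    continue
                if ch in "$*":
                    i += 1
                    continue
                if ch in "+-":
                    j = i + 1
                    while j < len(bases_str) and bases_str[j].isdigit():
                        j += 1
                    i = j + int(bases_str[i + 1 : j])
                    continue
                if ch in ".,":
                    bases.append(ref)
                    orients.append(1 if ch == "." else -1)
                elif ch.upper() in "ACGTN":
                    bases.append(ch.upper())
                    orients.append(1 if ch.isupper() else -1)
                i += 1
            quals = [ord(q) - 33 for q in quals_str[: len(bases)]]
            n = len(bases)
            yield PileupSite(
                chrom,
                pos,
                ref,
                np.array(bases),
                np.array(quals, dtype=np.int64),
                np.full(n, 30, dtype=np.int64),
                np.array(orients, dtype=np.int64),
                np.full(n, 30, dtype=np.int64),
                np.full(n, 30, dtype=np.int64),
            )
            continue
        reads = parts[3].split() if len(parts) > 3 and parts[3] else []
        bases, quals, mapqs, orients, p5s, p3s = [], [], [], [], [], []
        for r in reads:
            fields = r.split(":")
            if len(fields) != 6:
                raise PileupParseError(
                    f"line {lineno}: read tuple {r!r} must have 6 fields"
                )
            b, q, mq, o, p5, p3 = fields
            bases.append(b.upper())
            try:
                quals.append(int(q))
                mapqs.append(int(mq))
                p5s.append(int(p5))
                p3s.append(int(p3))
            except ValueError as e:
                raise PileupParseError(f"line {lineno}: bad numeric field in {r!r}") from e
            if o not in "+-":
                raise PileupParseError(f"line {lineno}: bad orientation {o!r}")
            orients.append(1 if o == "+" else -1)
        yield PileupSite(
            chrom,
            pos,
            ref,
            np.array(bases),
            np.array(quals, dtype=np.int64),
            np.array(mapqs, dtype=np.int64),
            np.array(orients, dtype=np.int64),
            np.array(p5s, dtype=np.int64),
            np.array(p3s, dtype=np.int64),
        )


# ---------------------------------------------------------------------------
# region calling and VCF output
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##source=paleodog-damcall
##FILTER=<ID=lowdepth,Description="Effective depth below minimum">
##INFO=<ID=HETDEM,Number=0,Type=Flag,Description="Heterozygote demoted to homozygote under the GQ threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Effective depth after filters">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def _vcf_record(call: GenotypeCall) -> str:
    ref = call.ref
    if call.genotype is None:
        return (
            f"{call.chrom}\t{call.pos}\t.\t{ref}\t.\t.\tlowdepth\t.\t"
            f"GT:GQ:DP\t./.:0:{call.depth}"
        )
    alts = []
    for a in call.genotype:
        if a != ref and a not in alts:
            alts.append(a)
    alleles = [ref] + alts
    gt = "/".join(str(alleles.index(a)) for a in sorted(call.genotype, key=alleles.index))
    alt_field = ",".join(alts) if alts else "."
    info = "HETDEM" if "het-demoted" in call.filters else "."
    return (
        f"{call.chrom}\t{call.pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t{info}\t"
        f"GT:GQ:DP\t{gt}:{int(round(call.gq))}:{call.depth}"
    )


def call_region(
    sites: Iterable[PileupSite],
    damage: DamageModel | None,
    *,
    min_depth: int = MIN_DEPTH,
    min_het_gq: float = MIN_HET_GQ,
) -> list[GenotypeCall]:
    return [
        call_site(site_likelihoods(s, damage), min_depth=min_depth, min_het_gq=min_het_gq)
        for s in sites
    ]


def write_vcf(calls: Iterable[GenotypeCall], out: TextIO) -> None:
    out.write(VCF_HEADER)
    for call in calls:
        out.write(_vcf_record(call) + "\n")
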