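"""Divergence dating from exclusive derived-allele sharing.

The estimator compares how many derived alleles an ancient dog shares
exclusively with European village dogs against how many European and Indian
village dogs share exclusively with each other.  Under a bifurcating
(((Ancient, Europe), India), Asia) history with an Asian admixture pulse into
the ancient lineage, the expected ratio of those two counts is a monotone
function of the ancient-European divergence time tau1 (in expected mutations
per site), so an observed ratio R inverts to a divergence time.  The sample's
radiocarbon age then bounds the yearly mutation rate from above
(mu <= g * tau1 / age) and calibrates divergence times into years
(years = g * tau / mu).

The expectation is computed exactly as expected coalescent branch lengths
subtending each sharing pattern, via a continuous-time Markov chain on
lineage partitions integrated piecewise over the demographic epochs.  An
independent discrete-event Monte-Carlo simulator of the same structured
coalescent acts as the module's ground truth and as the generator for
synthetic genotype panels.

Model populations and bit assignments: ANC (bit 0), EUR (bit 1), IND (bit 2),
ASIA (bit 3); one haploid lineage each.  Pattern bitmasks: derived shared
exclusively by ANC+EUR = 0b0011, by EUR+IND = 0b0110.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from .fstats import weighted_block_jackknife
from .simdata import GenotypePanel, MISSING, _assign_alleles

__all__ = [
    "CoalParams",
    "SharingCounts",
    "RatioEstimate",
    "Tau1Estimate",
    "CalibrationResult",
    "HaploidPanel",
    "haploidize",
    "count_sharing_patterns",
    "sharing_ratio",
    "expected_ratio",
    "expected_pattern_lengths",
    "solve_tau1",
    "mu_upper",
    "calibrate_time",
    "simulate_pattern_lengths",
    "simulate_dating_panel",
    "synthetic_posterior",
    "DATING_POPS",
]

DATING_POPS = ("ANC", "EUR", "IND", "ASIA")
_A, _E, _I, _S = 1, 2, 4, 8
MASK_ANC_EUR = _A | _E
MASK_EUR_IND = _E | _I
MASK_ANC_EUR_ASIA = _A | _E | _S
MASK_EUR_IND_ASIA = _E | _I | _S
_ALL = 15


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalParams:
    """Mutation-scaled demography conditioning the sharing-ratio expectation.

    theta1: size of the European/Boxer ancestral population (the environment
        of the ancient+European pair between tau1 and P2); theta2: size of the
        European/Indian ancestral population on [P2, P3]; theta3: size of the
        root population above P3 (defaults to theta2 when not given);
        P0: Europe/Boxer divergence (must not exceed tau1; the Boxer lineage
        is unsampled so P0 only constrains ordering); P2: Europe/India
        divergence; P3: (Europe,India)/Asia divergence; alpha: Asian
        admixture proportion in the ancient lineage; tau1: ancient-European
        divergence (the parameter being estimated; may be None while solving).
    """

    theta1: float
    theta2: float
    p0: float
    p2: float
    p3: float
    alpha: float
    tau1: float | None = None
    theta3: float | None = None

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("theta1 and theta2 must be > 0")
        if self.theta3 is not None and self.theta3 <= 0:
            raise ValueError("theta3 must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if not 0.0 < self.p0 <= self.p2 <= self.p3:
            raise ValueError("require 0 < P0 <= P2 <= P3")
        if self.tau1 is not None and not self.p0 <= self.tau1 <= self.p2:
            raise ValueError("require P0 <= tau1 <= P2")

    @property
    def root_theta(self) -> float:
        return self.theta2 if self.theta3 is None else self.theta3

    def with_tau1(self, tau1: float) -> "CoalParams":
        return replace(self, tau1=tau1)


# ---------------------------------------------------------------------------
# partition CTMC: exact expected pattern lengths
# ---------------------------------------------------------------------------

def _set_partitions(n: int) -> list[tuple[int, ...]]:
    """Partitions of n lineages; each partition is a sorted tuple of bitmasks."""
    def rec(elems: list[int]):
        if not elems:
            yield []
            return
        head, tail = elems[0], elems[1:]
        for part in rec(tail):
            yield [[head]] + [list(b) for b in part]
            for i in range(len(part)):
                new = [list(b) for b in part]
                new[i].append(head)
                yield new
    out = []
    for part in rec(list(range(n))):
        masks = tuple(sorted(sum(1 << x for x in block) for block in part))
        out.append(masks)
    return sorted(set(out))


_STATES: list[tuple[int, ...]] = _set_partitions(4)
_STATE_INDEX = {s: i for i, s in enumerate(_STATES)}
_N_STATES = len(_STATES)  # 15


def _merge(state: tuple[int, ...], b1: int, b2: int) -> tuple[int, ...]:
    rest = [b for b in state if b != b1 and b != b2]
    return tuple(sorted(rest + [b1 | b2]))


def _generator(pair_rate: float, allowed_mask: int) -> np.ndarray:
    """CTMC generator: blocks b1, b2 may merge iff (b1|b2) is within allowed_mask."""
    Q = np.zeros((_N_STATES, _N_STATES))
    for si, s in enumerate(_STATES):
        for b1, b2 in itertools.combinations(s, 2):
            if (b1 | b2) & ~allowed_mask:
                continue
            ti = _STATE_INDEX[_merge(s, b1, b2)]
            Q[si, ti] += pair_rate
            Q[si, si] -= pair_rate
    return Q


def _occupation_finite(Q: np.ndarray, p0: np.ndarray, duration: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(occupation time per state, distribution at epoch end) on [0, duration]."""
    if duration <= 0:
        return np.zeros(_N_STATES), p0
    n = _N_STATES
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = Q
    M[:n, n:] = np.eye(n)
    E = expm(M * duration)
    return p0 @ E[:n, n:], p0 @ E[:n, :n]


def _occupation_absorbing(Q: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Total expected occupation per transient state until absorption."""
    absorbing = np.isclose(np.diag(Q), 0.0)
    occ = np.zeros(_N_STATES)
    t_idx = np.flatnonzero(~absorbing)
    if len(t_idx) == 0:
        return occ
    Qtt = Q[np.ix_(t_idx, t_idx)]
    occ[t_idx] = np.linalg.solve(-Qtt.T, p0[t_idx])
    return occ


def _block_lengths_from_occupation(occ: np.ndarray) -> np.ndarray:
    """Accumulate state occupation into per-bitmask block existence time."""
    L = np.zeros(16)
    for si, s in enumerate(_STATES):
        for b in s:
            L[b] += occ[si]
    return L


@lru_cache(maxsize=256)
def _tail_lengths(theta2: float, theta3: float, d2: float, entry: tuple[int, ...],
                  epoch2_mask: int) -> tuple[np.ndarray, float]:
    """Expected block lengths from P2 onward, given the partition entering P2.

    Independent of tau1, so cached: the tau1 solve only re-evaluates the
    cheap closed-form epoch below P2.  Returns (lengths[16], unused).
    """
    p0 = np.zeros(_N_STATES)
    p0[_STATE_INDEX[entry]] = 1.0
    Q2 = _generator(2.0 / theta2, epoch2_mask)
    occ2, p_at_p3 = _occupation_finite(Q2, p0, d2)
    Q3 = _generator(2.0 / theta3, _ALL)
    occ3 = _occupation_absorbing(Q3, p_at_p3)
    return _block_lengths_from_occupation(occ2 + occ3), 0.0


_SINGLETONS = (1, 2, 4, 8)
_ENTRY_ALL = tuple(sorted(_SINGLETONS))
_ENTRY_MERGED = tuple(sorted((_A | _E, _I, _S)))
_EUR_EPOCH2_MASK = _A | _E | _I  # ANC (European-side), EUR, IND share theta2
_ASIA_EPOCH2_MASK = _E | _I      # Asian-side ANC joins only above P3


def expected_pattern_lengths(params: CoalParams, *, anc_age: float = 0.0) -> np.ndarray:
    """Expected branch length (mutation units) subtending each lineage subset.

    Entry ``L[mask]`` is the expected length of branches whose descendants are
    exactly the populations in ``mask``; a mutation on such a branch produces
    a site derived in precisely those lineages.  ``anc_age`` truncates the
    ancient tip (it only shortens the ancient singleton branch; the
    pair-sharing lengths used by the ratio do not depend on it).
    """
    if params.tau1 is None:
        raise ValueError("tau1 must be set")
    tau1, p2, p3 = params.tau1, params.p2, params.p3
    if anc_age > tau1:
        raise ValueError("ancient sample age must not exceed tau1")
    th1, th2, th3 = params.theta1, params.theta2, params.root_theta
    d1, d2 = p2 - tau1, p3 - p2

    # European-side path: ANC and EUR may coalesce on [tau1, P2] at rate 2/theta1
    r1 = 2.0 / th1
    q1 = np.exp(-r1 * d1)                  # P(no ANC-EUR coalescence below P2)
    occ_sing = (1.0 - q1) / r1             # time both singletons survive in epoch 1
    L_eur = np.zeros(16)
    L_eur[_A] += (tau1 - anc_age) + occ_sing
    L_eur[_E] += tau1 + occ_sing
    L_eur[_I] += tau1 + d1
    L_eur[_S] += tau1 + d1
    L_eur[_A | _E] += d1 - occ_sing        # merged-block time within epoch 1
    tail_merged, _ = _tail_lengths(th2, th3, d2, _ENTRY_MERGED, _EUR_EPOCH2_MASK)
    tail_sing, _ = _tail_lengths(th2, th3, d2, _ENTRY_ALL, _EUR_EPOCH2_MASK)
    L_eur += (1.0 - q1) * tail_merged + q1 * tail_sing

    # Asian-side path: ANC is frozen below P3
    L_asia = np.zeros(16)
    L_asia[_A] += p2 - anc_age
    L_asia[_E] += p2
    L_asia[_I] += p2
    L_asia[_S] += p2
    tail_asia, _ = _tail_lengths(th2, th3, d2, _ENTRY_ALL, _ASIA_EPOCH2_MASK)
    L_asia += tail_asia

    a = params.alpha
    L = (1.0 - a) * L_eur + a * L_asia
    L[0] = 0.0
    L[_ALL] = 0.0  # branches above the sample MRCA are invisible after polarization
    return L


def expected_ratio(params: CoalParams, *, strict: bool = True) -> float:
    """E[count(ANC+EUR exclusive)] / E[count(EUR+IND exclusive)].

    With ``strict`` the counted patterns require ASIA ancestral; otherwise the
    patterns also including ASIA contribute to both numerator and denominator.
    """
    L = expected_pattern_lengths(params)
    num = L[MASK_ANC_EUR]
    den = L[MASK_EUR_IND]
    if not strict:
        num += L[MASK_ANC_EUR_ASIA]
        den += L[MASK_EUR_IND_ASIA]
    return float(num / den)


# ---------------------------------------------------------------------------
# independent Monte-Carlo simulator (discrete-event structured coalescent)
# ---------------------------------------------------------------------------

_PAIR_SLOTS = list(itertools.combinations(range(4), 2))


def _epoch_events(
    masks: np.ndarray,
    alive: np.ndarray,
    t: np.ndarray,
    end: float,
    pair_rate: float,
    allowed_fn,
    L: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Advance all replicates through one epoch, accruing block lengths.

    ``masks``: (n, 4) block bitmasks; ``alive``: (n, 4) liveness; ``t``: (n,)
    current times; ``allowed_fn(m1, m2) -> bool array`` gates mergers.
    Mutates masks/alive/t/L in place; on return t == end (or all absorbed for
    an infinite epoch).
    """
    n = len(t)
    finite = np.isfinite(end)
    while True:
        # allowed pair slots per replicate
        allowed = np.zeros((n, len(_PAIR_SLOTS)), dtype=bool)
        for k, (i, j) in enumerate(_PAIR_SLOTS):
            allowed[:, k] = (
                alive[:, i] & alive[:, j] & allowed_fn(masks[:, i], masks[:, j])
            )
        m = allowed.sum(axis=1)
        active = m > 0
        if not finite and not active.any():
            break
        dt = np.full(n, np.inf)
        if active.any():
            dt[active] = rng.exponential(1.0, size=int(active.sum())) / (
                m[active] * pair_rate
            )
        t_event = t + dt
        if finite:
            fire = t_event < end
            t_stop = np.minimum(t_event, end)
        else:
            fire = active
            t_stop = np.where(fire, t_event, t)
        # accrue alive-block lengths up to the event (or the epoch end)
        seg = t_stop - t
        acc = seg > 0
        if acc.any():
            rep_idx, blk_idx = np.nonzero(alive & acc[:, None])
            np.add.at(L, (rep_idx, masks[rep_idx, blk_idx]), seg[rep_idx])
        t[:] = t_stop
        if not fire.any():
            break
        # choose a uniform allowed pair for each firing replicate
        f_idx = np.flatnonzero(fire)
        cum = np.cumsum(allowed[f_idx], axis=1)
        pick = rng.random(len(f_idx))[:, None] * cum[:, -1:]
        slot = (pick >= cum).sum(axis=1)
        for k, (i, j) in enumerate(_PAIR_SLOTS):
            sel = f_idx[slot == k]
            if len(sel):
                masks[sel, i] |= masks[sel, j]
                alive[sel, j] = False


def simulate_pattern_lengths(
    params: CoalParams,
    n_rep: int,
    seed: int,
    *,
    anc_age: float = 0.0,
) -> np.ndarray:
    """Monte-Carlo per-genealogy branch lengths subtending each lineage subset.

    Returns an (n_rep, 16) array; column ``mask`` holds, for each simulated
    genealogy, the total branch length whose mutations would be derived in
    exactly the populations of ``mask``.  This simulator shares no code with
    :func:`expected_pattern_lengths` and is the module's ground truth.
    """
    if params.tau1 is None:
        raise ValueError("tau1 must be set")
    rng = np.random.default_rng(seed)
    tau1, p2, p3 = params.tau1, params.p2, params.p3
    L = np.zeros((n_rep, 16))
    masks = np.tile(np.array([_A, _E, _I, _S]), (n_rep, 1)).astype(np.int64)
    alive = np.ones((n_rep, 4), dtype=bool)
    t = np.zeros(n_rep)
    asian_side = rng.random(n_rep) < params.alpha

    # tip branches below tau1 (no coalescence possible)
    L[:, _A] += tau1 - anc_age
    for m in (_E, _I, _S):
        L[:, m] += tau1
    t[:] = tau1

    def allowed_epoch1(m1, m2):
        ok = ((m1 | m2) & ~(_A | _E)) == 0
        return ok & ~asian_side

    def allowed_epoch2(m1, m2):
        eur_ok = ((m1 | m2) & ~_EUR_EPOCH2_MASK) == 0
        asia_ok = ((m1 | m2) & ~_ASIA_EPOCH2_MASK) == 0
        return np.where(asian_side, asia_ok, eur_ok)

    def allowed_epoch3(m1, m2):
        return np.ones_like(m1, dtype=bool)

    _epoch_events(masks, alive, t, p2, 2.0 / params.theta1, allowed_epoch1, L, rng)
    _epoch_events(masks, alive, t, p3, 2.0 / params.theta2, allowed_epoch2, L, rng)
    _epoch_events(masks, alive, t, np.inf, 2.0 / params.root_theta, allowed_epoch3, L, rng)
    L[:, 0] = 0.0
    L[:, _ALL] = 0.0
    return L


def simulate_dating_panel(
    params: CoalParams,
    n_sites: int,
    seed: int,
    *,
    n_genealogies: int | None = None,
    block_size: int = 500,
    anc_age: float = 0.0,
) -> GenotypePanel:
    """Pseudo-haploid genotype panel of ANC/EUR/IND/ASIA with ``n_sites`` sites.

    Sites are segregating variants: ``n_sites`` mutations are allocated across
    simulated genealogies proportionally to branch length (the fixed-S
    infinite-sites scheme), so genealogies hosting a site are correctly
    length-biased.  Samples are single chromosomes encoded as homozygous
    dosages (0/2), matching the estimator's use of one chromosome per
    population.
    """
    if n_genealogies is None:
        n_genealogies = max(n_sites, 1000)
    L = simulate_pattern_lengths(params, n_genealogies, seed, anc_age=anc_age)
    rng = np.random.default_rng(seed + 1)
    cells = L[:, 1:15].ravel()
    counts = rng.multinomial(n_sites, cells / cells.sum())
    site_pattern = np.repeat(np.tile(np.arange(1, 15), n_genealogies), counts)
    G = np.empty((n_sites, 4), dtype=np.int8)
    for j, bit in enumerate((_A, _E, _I, _S)):
        G[:, j] = np.where(site_pattern & bit, 2, 0)
    anc, der = _assign_alleles(n_sites, rng)
    return GenotypePanel(
        chrom=np.repeat("1", n_sites),
        pos=np.arange(1, n_sites + 1, dtype=np.int64),
        block_id=np.arange(n_sites, dtype=np.int64) // block_size,
        samples=list(DATING_POPS),
        sample_pops=list(DATING_POPS),
        genotypes=G,
        polarized=True,
        ancestral_allele=anc,
        derived_allele=der,
    )


# ---------------------------------------------------------------------------
# haploidization and pattern counting
# ---------------------------------------------------------------------------

@dataclass
class HaploidPanel:
    """One sampled chromosome per population; alleles in {0,1}, -1 missing."""

    pos: np.ndarray
    block_id: np.ndarray
    pops: list[str]
    alleles: np.ndarray  # (n_sites, n_pops)
    polarized: bool = True


def haploidize(panel: GenotypePanel, populations: list[str], seed: int) -> HaploidPanel:
    """Draw a single chromosome per population (first sample of each).

    Heterozygous dosages contribute a fair-coin allele; missing genotypes
    propagate as missing and are dropped site-wise by downstream counting.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    rng = np.random.default_rng(seed)
    cols = []
    for pop in populations:
        idx = panel.pop_indices(pop)
        if len(idx) == 0:
            raise KeyError(f"population {pop!r} not in panel")
        dos = panel.genotypes[:, idx[0]].astype(np.int8)
        allele = np.where(dos == 2, 1, 0).astype(np.int8)
        het = dos == 1
        if het.any():
            allele[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
        allele[dos == MISSING] = -1
        cols.append(allele)
    return HaploidPanel(
        pos=panel.pos.copy(),
        block_id=panel.block_id.copy(),
        pops=list(populations),
        alleles=np.column_stack(cols),
        polarized=panel.polarized,
    )


@dataclass
class SharingCounts:
    """Per-block exclusive-sharing tallies for the ratio estimator."""

    block_ids: np.ndarray
    n_anc_eur: np.ndarray
    n_eur_ind: np.ndarray
    n_sites: np.ndarray | None = None  # usable sites per block (jackknife weights)

    @property
    def total_anc_eur(self) -> int:
        return int(self.n_anc_eur.sum())

    @property
    def total_eur_ind(self) -> int:
        return int(self.n_eur_ind.sum())


def count_sharing_patterns(
    hap: HaploidPanel,
    *,
    pops: tuple[str, str, str, str] = DATING_POPS,
    strict: bool = True,
    modern_ascertainment: bool = True,
) -> SharingCounts:
    """Tally derived alleles shared exclusively by ANC+EUR vs by EUR+IND.

    ``n_anc_eur``: derived in the ancient and European chromosomes, ancestral
    in the Indian (and, when ``strict``, the Asian) chromosome; ``n_eur_ind``
    mirrors with ancient and Indian swapped.  ``modern_ascertainment``
    restricts to sites variable among the modern chromosomes (EUR, IND,
    ASIA), the scheme that insulates the ratio from genotyping error private
    to the ancient sample.  Complete-case: sites missing in any used
    chromosome are dropped.
    """
    if not hap.polarized:
        raise ValueError("panel must be polarized (derived state defined by outgroup)")
    idx = {p: hap.pops.index(p) for p in pops}
    a = hap.alleles[:, idx[pops[0]]]
    e = hap.alleles[:, idx[pops[1]]]
    i = hap.alleles[:, idx[pops[2]]]
    s = hap.alleles[:, idx[pops[3]]]
    ok = (a >= 0) & (e >= 0) & (i >= 0) & (s >= 0)
    if modern_ascertainment:
        ok &= ~((e == i) & (i == s))
    ae = ok & (a == 1) & (e == 1) & (i == 0)
    ei = ok & (e == 1) & (i == 1) & (a == 0)
    if strict:
        ae &= s == 0
        ei &= s == 0
    blocks, inv = np.unique(hap.block_id, return_inverse=True)
    return SharingCounts(
        block_ids=blocks,
        n_anc_eur=np.bincount(inv, weights=ae, minlength=len(blocks)).astype(np.int64),
        n_eur_ind=np.bincount(inv, weights=ei, minlength=len(blocks)).astype(np.int64),
        n_sites=np.bincount(inv, weights=ok, minlength=len(blocks)).astype(np.int64),
    )


@dataclass
class RatioEstimate:
    r: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int


def sharing_ratio(counts: SharingCounts, *, ci_z: float = 1.96) -> RatioEstimate:
    """R = sum(n_anc_eur) / sum(n_eur_ind) with weighted-jackknife CI."""
    if counts.total_eur_ind == 0:
        raise ZeroDivisionError("no EUR+IND exclusive sharing observed")
    est, se, g = weighted_block_jackknife(
        counts.n_anc_eur.astype(float),
        counts.n_eur_ind.astype(float),
        counts.block_ids,
        counts=None if counts.n_sites is None else counts.n_sites.astype(float),
    )
    if g < 2 or not np.isfinite(se):
        return RatioEstimate(float(est), np.nan, float(est), float(est), g)
    return RatioEstimate(
        float(est), float(se), float(est - ci_z * se), float(est + ci_z * se), g
    )


# ---------------------------------------------------------------------------
# tau1 solving and calibration
# ---------------------------------------------------------------------------

@dataclass
class Tau1Estimate:
    tau1: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_ci_solutions: int = 0
    n_out_of_range: int = 0


class RatioOutOfRangeError(ValueError):
    def __init__(self, target: float, lo: float, hi: float):
        super().__init__(
            f"target ratio {target:.6g} outside the attainable interval "
            f"[{lo:.6g}, {hi:.6g}] for these parameters"
        )
        self.attainable = (lo, hi)


def _solve_point(params: CoalParams, target: float, *, strict: bool,
                 xtol: float = 1e-12) -> float:
    """Bisection on the monotone-decreasing map tau1 -> expected_ratio."""
    lo, hi = params.p0, params.p2
    r_lo = expected_ratio(params.with_tau1(lo), strict=strict)
    r_hi = expected_ratio(params.with_tau1(hi), strict=strict)
    if not (r_hi <= target <= r_lo):
        raise RatioOutOfRangeError(target, min(r_lo, r_hi), max(r_lo, r_hi))
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if expected_ratio(params.with_tau1(mid), strict=strict) >= target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_tau1(
    r_target: RatioEstimate | float,
    params: CoalParams,
    *,
    strict: bool = True,
    posterior_draws: list[CoalParams] | None = None,
) -> Tau1Estimate:
    """Invert the expected sharing ratio for the divergence time tau1.

    The point solve bisects expected_ratio(tau1) = R on [P0, P2].  The CI is
    the range of solutions over (parameter draw, ratio-CI endpoint) pairs:
    with no posterior draws the point parameters are paired with the ratio CI
    endpoints alone.  Draws whose attainable ratio interval excludes an
    endpoint are skipped and counted.
    """
    if isinstance(r_target, RatioEstimate):
        r_point = r_target.r
        endpoints = [r_target.ci_low, r_target.ci_high]
    else:
        r_point = float(r_target)
        endpoints = []
    tau1 = _solve_point(params, r_point, strict=strict)
    draws = posterior_draws if posterior_draws else [params]
    sols = []
    skipped = 0
    if endpoints:
        for draw in draws:
            for endpoint in endpoints:
                try:
                    sols.append(_solve_point(draw, endpoint, strict=strict))
                except RatioOutOfRangeError:
                    skipped += 1
    if sols:
        return Tau1Estimate(tau1, min(sols), max(sols), len(sols), skipped)
    return Tau1Estimate(tau1, None, None, 0, skipped)


def mu_upper(tau1: float, sample_age_years: float, generation_years: float = 3.0) -> float:
    """Upper bound on the per-generation mutation rate from a sample's age.

    The sample must be younger than the divergence it sits below:
    age <= generation_years * tau1 / mu, so mu <= g * tau1 / age.
    """
    if tau1 <= 0 or sample_age_years <= 0 or generation_years <= 0:
        raise ValueError("inputs must be positive")
    return generation_years * tau1 / sample_age_years


def calibrate_time(tau: float, mu: float, generation_years: float = 3.0) -> float:
    """Mutation-scaled divergence to calendar years: years = g * tau / mu."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return generation_years * tau / mu


@dataclass
class CalibrationResult:
    tau1: float
    tau1_ci: tuple[float, float] | None
    mu_upper: float
    mu_upper_ci: tuple[float, float] | None
    years: float
    years_ci: tuple[float, float] | None
    sample_age_years: float
    generation_years: float
    mu_used: float


def calibrate(
    tau1: Tau1Estimate,
    sample_age_years: float,
    mu: float,
    generation_years: float = 3.0,
) -> CalibrationResult:
    """Assemble the full calibration: mu upper bound and calendar-year times."""
    bound = mu_upper(tau1.tau1, sample_age_years, generation_years)
    years = calibrate_time(tau1.tau1, mu, generation_years)
    has_ci = tau1.ci_low is not None
    return CalibrationResult(
        tau1=tau1.tau1,
        tau1_ci=(tau1.ci_low, tau1.ci_high) if has_ci else None,
        mu_upper=bound,
        mu_upper_ci=(
            mu_upper(tau1.ci_low, sample_age_years, generation_years),
            mu_upper(tau1.ci_high, sample_age_years, generation_years),
        ) if has_ci else None,
        years=years,
        years_ci=(
            calibrate_time(tau1.ci_low, mu, generation_years),
            calibrate_time(tau1.ci_high, mu, generation_years),
        ) if has_ci else None,
        sample_age_years=sample_age_years,
        generation_years=generation_years,
        mu_used=mu,
    )


# ---------------------------------------------------------------------------
# synthetic posterior draws (for CI machinery tests)
# ---------------------------------------------------------------------------

def synthetic_posterior(
    params: CoalParams, n_draws: int, seed: int, rel_sd: float = 0.05
) -> list[CoalParams]:
    """Independent truncated-normal draws around a parameter point.

    Stands in for resampled Bayesian posterior parameter estimates when only
    a point estimate is available; draws violating the model's ordering
    constraints are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    draws: list[CoalParams] = []
    guard = 0
    while len(draws) < n_draws:
        guard += 1
        if guard > 100 * n_draws:
            raise RuntimeError("posterior sampling rejected too many draws")
        try:
            draws.append(
                CoalParams(
                    theta1=params.theta1 * rng.lognormal(0.0, rel_sd),
                    theta2=params.theta2 * rng.lognormal(0.0, rel_sd),
                    p0=params.p0 * rng.lognormal(0.0, rel_sd),
                    p2=params.p2 * rng.lognormal(0.0, rel_sd),
                    p3=params.p3 * rng.lognormal(0.0, rel_sd),
                    alpha=float(np.clip(params.alpha + rng.normal(0.0, rel_sd * 0.5), 0, 1)),
                    tau1=None,
                    theta3=None if params.theta3 is None
                    else params.theta3 * rng.lognormal(0.0, rel_sd),
                )
            )
        except ValueError:
            continue
    return draws
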