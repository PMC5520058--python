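"""Post-mortem damage: misincorporation tables and the Weibull decay fit.

Ancient DNA carries cytosine deamination near fragment ends, observed as C>T
mismatches at 5' read positions and G>A at 3' positions (double-stranded
library chemistry).  The per-position damage probability is modelled as a
Weibull-type decay

    d(x) = a * exp(-(x**c) * b),    x = 1-based position from the read end,

with amplitude ``a`` in [0,1], rate ``b`` > 0 and shape ``c`` > 0; ``c = 1``
reduces to exponential decay, and the free-shape fit is never worse in
residual terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DamageTable",
    "WeibullDecay",
    "DamageModel",
    "tabulate_mismatches",
    "fit_weibull",
    "damage_probability",
]

DEFAULT_FIT_POSITIONS = 25
_B_DEFAULT = 0.3
_C_DEFAULT = 1.0


@dataclass
class WeibullDecay:
    """d(x) = a*exp(-(x^c)*b); non-increasing for b, c > 0."""

    a: float
    b: float
    c: float
    end: str = "5p_CT"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("amplitude a must be in [0,1]")
        if self.b <= 0 or self.c <= 0:
            raise ValueError("rate b and shape c must be > 0")

    def probability(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if (x < 1).any():
            raise ValueError("read positions are 1-based; x must be >= 1")
        if self.degenerate or self.a == 0.0:
            return np.zeros_like(x)
        return self.a * np.exp(-(x ** self.c) * self.b)


@dataclass
class DamageModel:
    five_prime: WeibullDecay
    three_prime: WeibullDecay

    @classmethod
    def flat(cls, a5: float, b5: float = _B_DEFAULT, c5: float = _C_DEFAULT,
             a3: float | None = None, b3: float | None = None, c3: float | None = None
             ) -> "DamageModel":
        """Convenience constructor; 3' parameters default to the 5' ones."""
        return cls(
            five_prime=WeibullDecay(a5, b5, c5, end="5p_CT", degenerate=a5 == 0),
            three_prime=WeibullDecay(
                a5 if a3 is None else a3,
                b5 if b3 is None else b3,
                c5 if c3 is None else c3,
                end="3p_GA",
                degenerate=(a5 if a3 is None else a3) == 0,
            ),
        )

    def to_json(self, path) -> None:
        import json

        obj = {
            end: {"a": d.a, "b": d.b, "c": d.c, "degenerate": d.degenerate}
            for end, d in [("five_prime", self.five_prime), ("three_prime", self.three_prime)]
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DamageModel":
        import json

        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            five_prime=WeibullDecay(end="5p_CT", **obj["five_prime"]),
            three_prime=WeibullDecay(end="3p_GA", **obj["three_prime"]),
        )


class DamageTable:
    """Per-position mismatch tallies from one read end.

    ``end`` is ``"5p_CT"`` (reference C read as T, position from the 5' end)
    or ``"3p_GA"`` (reference G read as A, position from the 3' end), always in
    template-strand coordinates: reverse-orientation reads are complemented so
    both strands tally into the same decay curve.
    """

    def __init__(self, end: str, max_pos: int):
        self.end = end
        self.positions = np.arange(1, max_pos + 1)
        self.opportunities = np.zeros(max_pos, dtype=np.int64)
        self.mismatches = np.zeros(max_pos, dtype=np.int64)

    @property
    def proportion(self) -> np.ndarray:
        """Mismatch proportion; NaN (missing) where there are no opportunities."""
        with np.errstate(invalid="ignore"):
            return np.where(
                self.opportunities > 0,
                self.mismatches / np.maximum(self.opportunities, 1),
                np.nan,
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("end\tpos\topportunities\tmismatches\tproportion\n")
            prop = self.proportion
            for i, x in enumerate(self.positions):
                p = "NA" if np.isnan(prop[i]) else f"{prop[i]:.6g}"
                fh.write(
                    f"{self.end}\t{x}\t{self.opportunities[i]}\t{self.mismatches[i]}\t{p}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "DamageTable":
        rows = []
        end = None
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                e, x, opp, mis, _ = line.rstrip("\n").split("\t")
                end = e
                rows.append((int(x), int(opp), int(mis)))
        table = cls(end or "5p_CT", max(r[0] for r in rows))
        for x, opp, mis in rows:
            table.opportunities[x - 1] = opp
            table.mismatches[x - 1] = mis
        return table

    @classmethod
    def from_mapdamage(cls, path, end: str) -> "DamageTable":
        """Tolerant reader for MapDamage-style misincorporation text.

        Expects whitespace-delimited columns including a position column
        (``Pos``) and either ``C>T``/``G>A`` counts with a reference-base
        count column (``C`` / ``G``), header lines starting with '#' skipped.
        """
        sub = "C>T" if end == "5p_CT" else "G>A"
        refbase = "C" if end == "5p_CT" else "G"
        rows = []
        with open(path) as fh:
            header = None
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                if header is None:
                    header = parts
                    continue
                rec = dict(zip(header, parts))
                if "Pos" not in rec:
                    continue
                rows.append(
                    (int(rec["Pos"]), int(rec.get(refbase, 0)), int(rec.get(sub, 0)))
                )
        table = cls(end, max(r[0] for r in rows))
        for x, opp, mis in rows:
            table.opportunities[x - 1] += opp
            table.mismatches[x - 1] += mis
        return table


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def tabulate_mismatches(
    stack,
    max_pos: int = 50,
) -> tuple[DamageTable, DamageTable]:
    """Tally strand-resolved C>T (from 5') and G>A (from 3') proportions.

    ``stack`` is an iterable of read-stack sites carrying per-read orientation
    and per-end positions (:class:`paleodog.simdata.ReadStackSite` or parsed
    pileup sites).  Reverse-orientation reads are complemented into template
    coordinates first, so both strands contribute to the same tables.
    """
    t5 = DamageTable("5p_CT", max_pos)
    t3 = DamageTable("3p_GA", max_pos)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for site in stack:
        ref = site.ref
        for i in range(len(site.bases)):
            obs = site.bases[i]
            if site.orients[i] > 0:
                r, o = ref, obs
            else:
                r, o = comp[ref], comp[obs]
            p5, p3 = int(site.pos5[i]), int(site.pos3[i])
            if r == "C" and p5 <= max_pos:
                t5.opportunities[p5 - 1] += 1
                if o == "T":
                    t5.mismatches[p5 - 1] += 1
            if r == "G" and p3 <= max_pos:
                t3.opportunities[p3 - 1] += 1
                if o == "A":
                    t3.mismatches[p3 - 1] += 1
    return t5, t3


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_weibull(
    table: DamageTable,
    *,
    fit_positions: int = DEFAULT_FIT_POSITIONS,
    subtract_error_floor: bool = True,
    fix_c: float | None = None,
) -> WeibullDecay:
    """Weighted least-squares fit of a*exp(-(x^c)*b) to a damage table.

    Residuals carry inverse-variance binomial weights,
    sqrt(opportunities / (p(1-p))); only the first ``fit_positions`` positions
    are used (damage is negligible deeper into the read).  When
    ``subtract_error_floor`` is set, the sequencing-error baseline estimated
    from interior positions (beyond the fit range) is subtracted before
    fitting.  ``fix_c=1`` gives the nested exponential-decay fit.
    """
    prop = table.proportion
    opp = table.opportunities.astype(float)
    x = table.positions.astype(float)

    floor = 0.0
    if subtract_error_floor:
        interior = (x > fit_positions) & (opp > 0)
        if interior.any():
            floor = float(
                np.nansum(prop[interior] * opp[interior]) / opp[interior].sum()
            )

    use = (x <= fit_positions) & (opp > 0)
    if use.sum() < 4:
        raise ValueError("need >= 4 positions with opportunities to fit")
    xs = x[use]
    ys = np.clip(prop[use] - floor, 0.0, 1.0)
    # variance floor keeps near-zero tail positions from dominating the fit
    ph = np.clip(ys, 1e-3, 1 - 1e-4)
    w = np.sqrt(opp[use] / (ph * (1 - ph)))

    if not (ys > 0).any():
        return WeibullDecay(0.0, _B_DEFAULT, _C_DEFAULT, end=table.end, degenerate=True)

    a0 = float(np.clip(ys[0], 1e-6, 1.0))
    head = ys[:10]
    pos_head = xs[:10][head > 0]
    val_head = head[head > 0]
    if len(val_head) >= 2:
        slope = -np.polyfit(pos_head, np.log(val_head), 1)[0]
        b0 = float(np.clip(slope, 1e-3, 50.0))
    else:
        b0 = _B_DEFAULT

    if fix_c is not None:
        def resid(p):
            a, b = p
            return w * (a * np.exp(-(xs ** fix_c) * b) - ys)

        sol = least_squares(
            resid, x0=[a0, b0], bounds=([0.0, 1e-6], [1.0, 50.0]), method="trf"
        )
        a, b = sol.x
        c = fix_c
    else:
        def resid(p):
            a, b, c = p
            return w * (a * np.exp(-(xs ** c) * b) - ys)

        sol = least_squares(
            resid,
            x0=[a0, b0, 1.0],
            bounds=([0.0, 1e-6, 1e-6], [1.0, 50.0, 5.0]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        a, b, c = sol.x
    degenerate = a < 1e-9
    return WeibullDecay(float(a), float(b), float(c), end=table.end, degenerate=bool(degenerate))


def fit_residual(table: DamageTable, decay: WeibullDecay,
                 fit_positions: int = DEFAULT_FIT_POSITIONS,
                 subtract_error_floor: bool = True) -> float:
    """Weighted sum of squared residuals of a fitted decay on its table."""
    prop = table.proportion
    opp = table.opportunities.astype(float)
    x = table.positions.astype(float)
    floor = 0.0
    if subtract_error_floor:
        interior = (x > fit_positions) & (opp > 0)
        if interior.any():
            floor = float(np.nansum(prop[interior] * opp[interior]) / opp[interior].sum())
    use = (x <= fit_positions) & (opp > 0)
    xs = x[use]
    ys = np.clip(prop[use] - floor, 0.0, 1.0)
    w = opp[use]
    pred = decay.a * np.exp(-(xs ** decay.c) * decay.b) if not decay.degenerate else 0.0
    return float(np.sum(w * (pred - ys) ** 2))


def damage_probability(model: DamageModel, end: str, x) -> np.ndarray:
    """Evaluate the decay for ``end`` in {"5p_CT", "3p_GA"} at position(s) x."""
    decay = model.five_prime if end == "5p_CT" else model.three_prime
    return decay.probability(x)
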