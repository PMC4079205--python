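"""Cn/Nc class substitution frequencies and neutral expectations.

Per splice-site position with consensus set Cn, the observed class-exit
frequency in one direction is

    q(Cn->Nc) = sum_{Z in Cn, X in Nc} #(Z->X)
                / sum_{Z in Cn, any X} #(Z->X)

(and symmetrically for Nc->Cn).  Within-class substitutions count toward
the opportunity denominator but not the numerator, so q estimates the
per-branch probability of leaving the class.  The neutral expectation is
the composition-weighted mean of per-nucleotide rates measured in matched
neutral control regions (intronic controls for intronic positions,
fourfold-degenerate-codon controls for exonic ones), after filtering
controls by a phyloP-like neutrality score.  Observed and expected counts
are compared by Fisher's exact test on the 2x2 substituted/conserved table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import ControlObservations, SubstitutionCounts
from .selection import clopper_pearson
from .sites import NUC_INDEX, NUCLEOTIDES, ConsensusTable, Role, position_role

log = logging.getLogger(__name__)

__all__ = [
    "RateEstimate",
    "NeutralRates",
    "class_frequency",
    "neutral_rates",
    "expected_frequency",
    "obs_vs_exp_test",
    "offset_table",
]

CN_TO_NC = "Cn->Nc"
NC_TO_CN = "Nc->Cn"

#: control provenance used for each position role
ROLE_PROVENANCE = {
    Role.INTRONIC: "intronic-control",
    Role.EXONIC: "fourfold-control",
}


@dataclass
class RateEstimate:
    """Observed class substitution frequency with an exact binomial CI."""

    direction: str
    k: int
    n: int
    q: float
    ci_low: float
    ci_high: float
    site_type: str | None = None
    offset: int | None = None


def _class_sets(consensus: ConsensusTable, site_type: str, offset: int):
    role = position_role(site_type, offset)
    if role in (Role.INVARIANT, Role.NO_CONSENSUS):
        raise ValueError(f"{site_type} {offset:+d} has role {role.value}; no q defined")
    cn = consensus.cn(site_type, offset)
    if cn is None:
        raise ValueError(f"no Cn set defined at {site_type} {offset:+d}")
    nc = frozenset(NUCLEOTIDES) - cn
    return cn, nc


def class_frequency(
    counts: SubstitutionCounts,
    consensus: ConsensusTable,
    site_type: str,
    offset: int,
    direction: str,
    alpha: float = 0.05,
) -> RateEstimate:
    """Observed q for one offset and direction from a counts table."""
    cn, nc = _class_sets(consensus, site_type, offset)
    src, dst = (cn, nc) if direction == CN_TO_NC else (nc, cn)
    if direction not in (CN_TO_NC, NC_TO_CN):
        raise ValueError(f"unknown direction {direction!r}")
    mat = counts.matrix(offset)
    src_idx = [NUC_INDEX[x] for x in src]
    dst_idx = [NUC_INDEX[x] for x in dst]
    n = int(mat[src_idx, :].sum())
    k = int(mat[np.ix_(src_idx, dst_idx)].sum())
    if n == 0:
        return RateEstimate(direction, 0, 0, float("nan"), float("nan"), float("nan"),
                            site_type, offset)
    lo, hi = clopper_pearson(k, n, alpha)
    return RateEstimate(direction, k, n, k / n, lo, hi, site_type, offset)


class NeutralRates:
    """Per-nucleotide neutral substitution rates from filtered controls.

    For ancestral nucleotide Z and a target set T, r_Z(T) is the fraction of
    retained control positions with ancestor Z whose descendant lies in T;
    rates are additive over disjoint target sets.  One 4x4 count matrix is
    kept per control provenance.
    """

    def __init__(self, counts: dict[str, np.ndarray]):
        self.counts = {k: np.asarray(v, dtype=np.int64) for k, v in counts.items()}
        for prov, mat in self.counts.items():
            if mat.shape != (4, 4):
                raise ValueError(f"control counts for {prov!r} must be 4x4")

    def opportunities(self, Z: str, provenance: str) -> int:
        return int(self.counts[provenance][NUC_INDEX[Z]].sum())

    def exits(self, Z: str, targets, provenance: str) -> int:
        row = self.counts[provenance][NUC_INDEX[Z]]
        return int(sum(row[NUC_INDEX[x]] for x in targets if x != Z))

    def rate(self, Z: str, targets, provenance: str) -> float:
        n = self.opportunities(Z, provenance)
        if n == 0:
            raise ValueError(
                f"no control opportunities for ancestral {Z} in {provenance}"
            )
        return self.exits(Z, targets, provenance) / n


def neutral_rates(
    control_obs: ControlObservations,
    score_threshold: float = 0.6,
    keep_below: bool = True,
    exclude_cpg: bool = False,
) -> NeutralRates:
    """Aggregate control observations into per-nucleotide neutral rates.

    ``keep_below=True`` retains positions with |score| < threshold (the
    reading that yields neutrally evolving controls); the opposite reading
    is selectable for comparison.  Ambiguous reconstructions are dropped;
    with ``exclude_cpg`` ancestral-CpG-context positions are dropped too.
    """
    counts: dict[str, np.ndarray] = {}
    for prov, pool in control_obs.pools.items():
        keep = pool["anc"] >= 0
        absd = np.abs(pool["score"])
        keep &= (absd < score_threshold) if keep_below else (absd >= score_threshold)
        if exclude_cpg:
            keep &= ~pool["cpg"]
        if not keep.any():
            raise ValueError(f"control pool {prov!r} is empty after filtering")
        mat = np.zeros((4, 4), dtype=np.int64)
        np.add.at(mat, (pool["anc"][keep], pool["desc"][keep]), 1)
        counts[prov] = mat
    return NeutralRates(counts)


def expected_frequency(
    ss_ancestral_composition: dict[str, int],
    neutral: NeutralRates,
    consensus: ConsensusTable,
    site_type: str,
    offset: int,
    direction: str,
    n_obs: int | None = None,
    provenance: str | None = None,
):
    """Neutral expectation of q at one offset, matched by nucleotide.

    q_exp = sum_Z w_Z * r_Z(T), where Z ranges over the ancestral class
    members observed at this offset, w_Z are composition weights, and T is
    the complementary class.  Returns (q_exp, k_exp, n_exp): expected counts
    scale q_exp by the observed opportunity count ``n_obs`` when given.
    """
    cn, nc = _class_sets(consensus, site_type, offset)
    src, dst = (cn, nc) if direction == CN_TO_NC else (nc, cn)
    if provenance is None:
        provenance = ROLE_PROVENANCE[position_role(site_type, offset)]
    weights = {Z: ss_ancestral_composition.get(Z, 0) for Z in src}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(
            f"no ancestral class members observed at {site_type} {offset:+d}"
        )
    q_exp = sum(w * neutral.rate(Z, dst, provenance) for Z, w in weights.items())
    q_exp /= total
    n_e = float(n_obs) if n_obs is not None else float(total)
    return q_exp, q_exp * n_e, n_e


def control_class_counts(
    composition: dict[str, int],
    neutral: NeutralRates,
    consensus: ConsensusTable,
    site_type: str,
    offset: int,
    direction: str,
    provenance: str | None = None,
) -> tuple[int, int]:
    """Composition-matched control counts on the control sampling scale.

    n is the total number of retained control opportunities over the class
    members, and k the rounded composition-weighted expected exits; these
    feed the 2x2 Fisher comparison at the control's own sample size.
    """
    cn, nc = _class_sets(consensus, site_type, offset)
    src, dst = (cn, nc) if direction == CN_TO_NC else (nc, cn)
    if provenance is None:
        provenance = ROLE_PROVENANCE[position_role(site_type, offset)]
    q_exp, _, _ = expected_frequency(
        composition, neutral, consensus, site_type, offset, direction,
        provenance=provenance,
    )
    n_c = sum(neutral.opportunities(Z, provenance) for Z in src)
    return int(round(q_exp * n_c)), n_c


def obs_vs_exp_test(k_obs: int, n_obs: int, k_exp: int, n_exp: int) -> float:
    """Two-sided Fisher exact p for the substituted/conserved 2x2 table."""
    vals = [k_obs, n_obs, k_exp, n_exp]
    if any(v < 0 for v in vals):
        raise ValueError("counts must be non-negative")
    k_obs, n_obs, k_exp, n_exp = (int(round(v)) for v in vals)
    if k_obs > n_obs or k_exp > n_exp:
        raise ValueError("k must not exceed n")
    table = [[k_obs, n_obs - k_obs], [k_exp, n_exp - k_exp]]
    margins = (k_obs + k_exp, (n_obs - k_obs) + (n_exp - k_exp), n_obs, n_exp)
    if any(m == 0 for m in margins):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(p)
    out = np.full_like(p, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def offset_table(
    counts: SubstitutionCounts,
    neutral: NeutralRates,
    consensus: ConsensusTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-offset observed/expected frequency table for both directions.

    Columns mirror the written TSV contract; the BH-adjusted p column is an
    extension beyond the raw per-offset Fisher tests.
    """
    rows = []
    site_type = counts.site_type
    for off in consensus.scored_offsets(site_type):
        comp = counts.composition(off)
        for direction in (CN_TO_NC, NC_TO_CN):
            est = class_frequency(counts, consensus, site_type, off, direction, alpha)
            if est.n == 0:
                continue
            q_exp, k_e, n_e = expected_frequency(
                comp, neutral, consensus, site_type, off, direction, n_obs=est.n
            )
            k_c, n_c = control_class_counts(
                comp, neutral, consensus, site_type, off, direction
            )
            p = obs_vs_exp_test(est.k, est.n, k_c, n_c)
            rows.append(
                {
                    "site_type": site_type,
                    "offset": off,
                    "direction": direction,
                    "k": est.k,
                    "n": est.n,
                    "q": est.q,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "q_exp": q_exp,
                    "p_fisher": p,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bh"] = _bh_adjust(df["p_fisher"].to_numpy())
    return df


def pooled_class_counts(
    counts: SubstitutionCounts,
    neutral: NeutralRates,
    consensus: ConsensusTable,
    direction: str,
    alpha: float = 0.05,
) -> tuple[RateEstimate, float]:
    """Pool k and n over all scored offsets; q_exp is opportunity-weighted.

    Pooled estimates match the opportunity-weighted mean of the per-offset
    estimates by construction.
    """
    site_type = counts.site_type
    k_tot = n_tot = 0
    k_exp_tot = 0.0
    for off in consensus.scored_offsets(site_type):
        est = class_frequency(counts, consensus, site_type, off, direction, alpha)
        if est.n == 0:
            continue
        comp = counts.composition(off)
        q_exp, k_e, _ = expected_frequency(
            comp, neutral, consensus, site_type, off, direction, n_obs=est.n
        )
        k_tot += est.k
        n_tot += est.n
        k_exp_tot += k_e
    if n_tot == 0:
        raise ValueError("no opportunities at any scored offset")
    lo, hi = clopper_pearson(k_tot, n_tot, alpha)
    pooled = RateEstimate(direction, k_tot, n_tot, k_tot / n_tot, lo, hi, site_type, None)
    return pooled, k_exp_tot / n_tot
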