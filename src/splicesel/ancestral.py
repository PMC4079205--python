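"""Maximum-parsimony ancestral reconstruction and substitution counting.

For the three-taxon topology ((reference, sister), outgroup) with a single
internal node, the parsimony ancestor of the reference/sister clade is the
state minimizing the number of changes over the three pendant branches;
when two states tie, the column is ambiguous and contributes to no count.
Substitutions are polarized on the reference branch only: each resolved
column increments #(ancestor -> reference descendant), with the diagonal
holding conserved counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sites import (
    NUC_INDEX,
    NUCLEOTIDES,
    ConsensusTable,
    Role,
    SpliceSiteRecord,
    position_role,
    site_offsets,
)
from .simulate import ControlBlock, TripletEnsemble

__all__ = [
    "parsimony_ancestor",
    "parsimony_ancestor_codes",
    "SubstitutionCounts",
    "count_substitutions",
    "ControlObservations",
    "reconstruct_controls",
]

_MISSING = -1


def _encode(symbol) -> int:
    if symbol is None:
        return _MISSING
    s = str(symbol).upper()
    if s in NUC_INDEX:
        return NUC_INDEX[s]
    if s in ("-", "N", ".", ""):
        return _MISSING
    raise ValueError(f"non-nucleotide symbol {symbol!r}")


def parsimony_ancestor_codes(
    ref: np.ndarray, sister: np.ndarray, outgroup: np.ndarray
) -> np.ndarray:
    """Vectorized parsimony over integer-coded states (missing < 0).

    Returns the ancestral code of the (ref, sister) clade, or -1 where the
    minimum is tied or any input is missing.
    """
    ref = np.asarray(ref)
    sister = np.asarray(sister)
    outgroup = np.asarray(outgroup)
    costs = np.empty((4,) + ref.shape, dtype=np.int8)
    for a in range(4):
        costs[a] = (ref != a).astype(np.int8) + (sister != a) + (outgroup != a)
    best = costs.min(axis=0)
    anc = costs.argmin(axis=0).astype(np.int8)
    ties = (costs == best).sum(axis=0)
    invalid = (ref < 0) | (sister < 0) | (outgroup < 0) | (ties > 1)
    anc[invalid] = _MISSING
    return anc


def parsimony_ancestor(ref, sister, outgroup) -> str:
    """Parsimony ancestor of the (ref, sister) clade with one outgroup.

    Accepts single-letter nucleotides (A/C/G/T); gaps, N or None count as
    missing data.  Returns the ancestral nucleotide, or ``"ambiguous"`` when
    two ancestral states tie or data are missing.
    """
    codes = np.array(
        [[_encode(ref)], [_encode(sister)], [_encode(outgroup)]], dtype=np.int8
    )
    anc = parsimony_ancestor_codes(codes[0], codes[1], codes[2])[0]
    return "ambiguous" if anc < 0 else NUCLEOTIDES[anc]


@dataclass
class SubstitutionCounts:
    """Per-offset 4x4 ancestral -> descendant substitution counts.

    counts[j, Z, X] is the number of columns at offset j with parsimony
    ancestor Z and reference-lineage descendant X (diagonal = conserved).
    Ambiguous columns and CpG-excluded columns are tallied separately so
    that, per offset, counts + ambiguous + excluded = number of records.
    """

    site_type: str
    offsets: tuple[int, ...]
    counts: np.ndarray  # (n_offsets, 4, 4) int64
    ambiguous: np.ndarray  # (n_offsets,) int64
    excluded: np.ndarray  # (n_offsets,) int64
    n_records: int

    def matrix(self, offset: int) -> np.ndarray:
        return self.counts[self.offsets.index(offset)]

    def composition(self, offset: int) -> dict[str, int]:
        """Ancestral nucleotide counts at one offset (row sums)."""
        row = self.matrix(offset).sum(axis=1)
        return {NUCLEOTIDES[i]: int(row[i]) for i in range(4)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, off in enumerate(self.offsets):
            for z in range(4):
                for x in range(4):
                    c = int(self.counts[j, z, x])
                    if c:
                        rows.append(
                            {
                                "site_type": self.site_type,
                                "offset": off,
                                "ancestral": NUCLEOTIDES[z],
                                "descendant": NUCLEOTIDES[x],
                                "count": c,
                            }
                        )
        return pd.DataFrame(
            rows, columns=["site_type", "offset", "ancestral", "descendant", "count"]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _arrays_from_records(
    records: Sequence[SpliceSiteRecord],
    species: tuple[str, str, str] = ("ref", "sister", "outgroup"),
):
    if not records:
        raise ValueError("no records to count")
    site_type = records[0].site_type
    offsets = site_offsets(site_type)
    n_pos = len(offsets)
    arrs = []
    for sp in species:
        a = np.empty((len(records), n_pos), dtype=np.int8)
        for i, rec in enumerate(records):
            if rec.site_type != site_type:
                raise ValueError("mixed site types in one ensemble")
            seq = rec.seq_by_species[sp]
            if len(seq) != n_pos:
                raise ValueError(f"{rec.site_id}: sequence length mismatch")
            a[i] = [_encode(c) for c in seq]
        arrs.append(a)
    return site_type, offsets, arrs[0], arrs[1], arrs[2]


def _ancestor_for_counting(
    ref: np.ndarray, sister: np.ndarray, outgroup: np.ndarray, polarization: str
) -> np.ndarray:
    if polarization == "strict":
        # outgroup-corroborated subset of the parsimony solution: the
        # ancestor is called only where sister and outgroup agree, so that
        # column retention depends on the non-reference branches alone and
        # cannot correlate with the reference-branch event being counted
        anc = np.where((sister == outgroup) & (sister >= 0), sister, _MISSING)
        return np.where(ref >= 0, anc, _MISSING).astype(np.int8)
    if polarization == "parsimony":
        return parsimony_ancestor_codes(ref, sister, outgroup)
    raise ValueError(f"unknown polarization {polarization!r}")


def count_substitutions(
    data,
    consensus: ConsensusTable | None = None,
    exclude_cpg: bool = False,
    polarization: str = "strict",
) -> SubstitutionCounts:
    """Tabulate ancestral -> reference substitution counts per offset.

    ``data`` is either a TripletEnsemble or a sequence of SpliceSiteRecord
    carrying ref/sister/outgroup sequences.  Ambiguous reconstructions are
    dropped from every tally.  With the default ``strict`` polarization the
    ancestor is the shared sister/outgroup state and columns where the two
    disagree count as ambiguous; ``parsimony`` additionally resolves those
    columns by the Fitch rule wherever the minimum is unique, at the cost
    of a retention probability that depends on the reference branch.  With
    ``exclude_cpg``, any position that is part of a CG dinucleotide in the
    reconstructed ancestral sequence (a C followed by G, or a G preceded by
    C, on the transcribed strand) is excluded; positions whose CpG status
    cannot be assessed because a neighbor is ambiguous are retained.
    """
    if isinstance(data, TripletEnsemble):
        site_type, offsets = data.site_type, data.offsets
        ref, sister, outgroup = data.ref, data.sister, data.outgroup
    else:
        site_type, offsets, ref, sister, outgroup = _arrays_from_records(list(data))
    if not (ref.shape == sister.shape == outgroup.shape):
        raise ValueError("species arrays have mismatched shapes")

    anc = _ancestor_for_counting(ref, sister, outgroup, polarization)
    n, n_pos = anc.shape
    if exclude_cpg:
        c, g = NUC_INDEX["C"], NUC_INDEX["G"]
        cpg = np.zeros(anc.shape, dtype=bool)
        is_c = anc == c
        is_g = anc == g
        cpg[:, :-1] |= is_c[:, :-1] & is_g[:, 1:]
        cpg[:, 1:] |= is_g[:, 1:] & is_c[:, :-1]
    else:
        cpg = np.zeros(anc.shape, dtype=bool)

    counts = np.zeros((n_pos, 4, 4), dtype=np.int64)
    ambiguous = np.zeros(n_pos, dtype=np.int64)
    excluded = np.zeros(n_pos, dtype=np.int64)
    for j in range(n_pos):
        valid = anc[:, j] >= 0
        excl = valid & cpg[:, j]
        use = valid & ~excl
        ambiguous[j] = int((~valid).sum())
        excluded[j] = int(excl.sum())
        np.add.at(counts[j], (anc[use, j], ref[use, j]), 1)
    return SubstitutionCounts(
        site_type=site_type,
        offsets=tuple(offsets),
        counts=counts,
        ambiguous=ambiguous,
        excluded=excluded,
        n_records=n,
    )


@dataclass
class ControlObservations:
    """Reconstructed neutral-control positions, one pool per provenance.

    Each provenance maps to a dict of equal-length arrays: ``anc`` (parsimony
    ancestor, -1 ambiguous), ``desc`` (reference descendant), ``score``
    (neutrality score) and ``cpg`` (ancestral CpG-context flag).
    """

    pools: dict[str, dict[str, np.ndarray]]

    def to_frame(self) -> pd.DataFrame:
        lut = np.array(list(NUCLEOTIDES) + ["N"])
        frames = []
        for prov, pool in self.pools.items():
            frames.append(
                pd.DataFrame(
                    {
                        "provenance": prov,
                        "ancestral": lut[pool["anc"]],
                        "descendant": lut[pool["desc"]],
                        "score": pool["score"],
                        "cpg": pool["cpg"].astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def reconstruct_controls(
    controls: dict[str, ControlBlock], polarization: str = "strict"
) -> ControlObservations:
    """Reconstruct control ancestors (same polarization as the site counts)
    and flag CpG context.

    CpG context at controls uses the simulated ancestral neighbors (controls
    are isolated positions, so no reconstructed flanking sequence exists).
    """
    pools = {}
    c, g = NUC_INDEX["C"], NUC_INDEX["G"]
    for prov, block in controls.items():
        anc = _ancestor_for_counting(
            block.ref, block.sister, block.outgroup, polarization
        )
        cpg = ((anc == c) & (block.next_ == g)) | ((anc == g) & (block.prev == c))
        pools[prov] = {
            "anc": anc,
            "desc": block.ref.astype(np.int8),
            "score": block.score,
            "cpg": cpg,
        }
    return ControlObservations(pools=pools)


def control_observations_from_frame(
    df: pd.DataFrame, polarization: str = "strict"
) -> ControlObservations:
    """Rebuild ControlObservations from a long-format control TSV.

    Accepts either already-reconstructed columns (ancestral/descendant) or
    raw triplet columns (ref/sister/outgroup), in which case ancestors are
    reconstructed here with the requested polarization.
    """
    pools = {}
    c, g = NUC_INDEX["C"], NUC_INDEX["G"]
    for prov, sub in df.groupby("provenance"):
        if {"ref", "sister", "outgroup"} <= set(sub.columns):
            enc = lambda col: np.array([_encode(x) for x in sub[col]], dtype=np.int8)
            ref, sis, out = enc("ref"), enc("sister"), enc("outgroup")
            anc = _ancestor_for_counting(ref, sis, out, polarization)
            desc = ref
            if {"prev", "next"} <= set(sub.columns):
                prev, next_ = enc("prev"), enc("next")
                cpg = ((anc == c) & (next_ == g)) | ((anc == g) & (prev == c))
            else:
                cpg = np.zeros(len(sub), dtype=bool)
        else:
            anc = np.array([_encode(x) for x in sub["ancestral"]], dtype=np.int8)
            desc = np.array([_encode(x) for x in sub["descendant"]], dtype=np.int8)
            cpg = (
                sub["cpg"].to_numpy().astype(bool)
                if "cpg" in sub.columns
                else np.zeros(len(sub), dtype=bool)
            )
        score = (
            sub["score"].to_numpy(dtype=float)
            if "score" in sub.columns
            else np.zeros(len(sub))
        )
        pools[str(prov)] = {"anc": anc, "desc": desc, "score": score, "cpg": cpg}
    return ControlObservations(pools=pools)
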