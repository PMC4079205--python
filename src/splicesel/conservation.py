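"""Multispecies conservation depth and the (obs - exp)/exp contrast.

For one alignment column, the conservation depth of a target nucleotide set
is the phylogenetic distance L (Ks units) to the most distant species x
such that every species at distance <= L(x) carries a nucleotide from the
target set.  Depth is 0 when the nearest species already fails; species
tied at the failing distance are excluded along with it, and missing data
terminate the conserved prefix.  Depths are averaged over columns (columns
of depth 0 included), and contrasted against matched neutral control
columns as c = (obs - exp)/exp, with percentile bootstrap CIs over columns.

``c_nuc`` uses the specific reference nucleotide of each column as the
target; ``c_set`` uses the full Cn (or Nc) set of the position.  Control
columns are matched by reference-nucleotide identity and weighted by the
observed composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .simulate import PanelColumns
from .sites import NUC_INDEX, NUCLEOTIDES

__all__ = [
    "conservation_depth",
    "depth_profile",
    "ConservationResult",
    "conservation_contrast",
    "load_panel",
    "bootstrap_ci",
]


def depth_profile(
    states: np.ndarray, distances: np.ndarray, target_mask: np.ndarray
) -> np.ndarray:
    """Vectorized conservation depths for many columns.

    ``states``: (n_cols, n_species) integer codes, species ordered by
    non-decreasing distance; negative codes are missing data.
    ``target_mask``: either (4,) applied to every column or (n_cols, 4)
    per-column target sets.
    """
    states = np.asarray(states)
    distances = np.asarray(distances, dtype=float)
    if states.ndim != 2 or states.shape[1] != distances.size:
        raise ValueError("states must be (n_cols, n_species)")
    if distances.size == 0:
        raise ValueError("empty panel")
    target_mask = np.asarray(target_mask, dtype=bool)
    clipped = np.clip(states, 0, 3).astype(np.intp)
    if target_mask.ndim == 1:
        match = target_mask[clipped]
    else:
        match = np.take_along_axis(target_mask, clipped, axis=1)
    match &= states >= 0  # missing data never match
    mismatch = ~match
    any_fail = mismatch.any(axis=1)
    first_fail = mismatch.argmax(axis=1)
    min_fail = np.where(any_fail, distances[first_fail], np.inf)
    # deepest distance strictly below the first failure; ties at the failing
    # distance are excluded together with it
    j = np.searchsorted(distances, min_fail, side="left") - 1
    depth = np.where(j >= 0, distances[np.maximum(j, 0)], 0.0)
    depth = np.where(any_fail, depth, distances[-1])
    return depth


def conservation_depth(
    states: Sequence, distances: Sequence[float], target
) -> float:
    """Depth of one column; ``target`` is an iterable of nucleotides."""
    codes = np.array(
        [[NUC_INDEX.get(str(s).upper(), -1) for s in states]], dtype=np.int8
    )
    mask = np.zeros(4, dtype=bool)
    for nuc in target:
        mask[NUC_INDEX[str(nuc).upper()]] = True
    if not mask.any():
        raise ValueError("target set must not be empty")
    return float(depth_profile(codes, np.asarray(distances, float), mask)[0])


@dataclass
class ConservationResult:
    selector: str  # "nuc" | "set"
    obs: float
    exp: float
    c: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_ctrl: int


def _set_mask(nucs) -> np.ndarray:
    mask = np.zeros(4, dtype=bool)
    for n in nucs:
        mask[NUC_INDEX[str(n).upper()]] = True
    return mask


def conservation_contrast(
    obs: PanelColumns,
    controls: PanelColumns,
    selector: str,
    class_sets: Mapping[int, frozenset],
    B: int = 1000,
    seed: int = 0,
    chunk: int = 100,
) -> ConservationResult:
    """Contrast c = (obs - exp)/exp for one nucleotide class.

    ``class_sets`` maps offsets to the Cn (or Nc) set of that position;
    columns whose reference nucleotide does not belong to its position's
    class are excluded.  The expectation pairs each observed column with
    neutral control columns sharing its reference nucleotide (and, for the
    set selector, its class set), weighted by the observed composition.
    Bootstrap resamples observed and control columns jointly in each of the
    B trials.
    """
    if selector not in ("nuc", "set"):
        raise ValueError(f"unknown selector {selector!r}")
    offsets = np.asarray(obs.offsets)
    in_class = np.zeros(offsets.size, dtype=bool)
    set_key = {}  # offset -> frozenset
    for off, nucs in class_sets.items():
        sel = offsets == off
        if not sel.any():
            continue
        mask = _set_mask(nucs)
        in_class |= sel & mask[np.clip(obs.ref, 0, 3)]
        set_key[int(off)] = frozenset(str(n).upper() for n in nucs)
    idx_obs = np.flatnonzero(in_class)
    if idx_obs.size == 0:
        raise ValueError("no observed columns with a class reference nucleotide")

    dist = np.asarray(obs.distances, dtype=float)
    if selector == "nuc":
        tmask = np.zeros((idx_obs.size, 4), dtype=bool)
        tmask[np.arange(idx_obs.size), obs.ref[idx_obs].astype(np.intp)] = True
    else:
        tmask = np.zeros((idx_obs.size, 4), dtype=bool)
        for off, key in set_key.items():
            rows = offsets[idx_obs] == off
            tmask[rows] = _set_mask(key)
    obs_depth = depth_profile(obs.states[idx_obs], dist, tmask)

    # control depths per (group) where a group is a reference nucleotide for
    # "nuc", or a (class set, reference nucleotide) pair for "set"
    cdist = np.asarray(controls.distances, dtype=float)
    ctrl_ref = controls.ref.astype(np.intp)
    if selector == "nuc":
        group_of_obs = obs.ref[idx_obs].astype(np.intp)
        groups = np.unique(group_of_obs)
        ctrl_depths = {}
        ctrl_members = {}
        for gcode in groups:
            members = np.flatnonzero(ctrl_ref == gcode)
            if members.size == 0:
                raise ValueError(
                    f"no control columns with reference {NUCLEOTIDES[gcode]}"
                )
            mask = np.zeros(4, dtype=bool)
            mask[gcode] = True
            ctrl_depths[int(gcode)] = depth_profile(
                controls.states[members], cdist, mask
            )
            ctrl_members[int(gcode)] = members
        obs_groups = group_of_obs
    else:
        key_codes = {}
        obs_groups = np.empty(idx_obs.size, dtype=np.int64)
        ctrl_depths = {}
        ctrl_members = {}
        next_code = 0
        for off, key in set_key.items():
            rows = np.flatnonzero(offsets[idx_obs] == off)
            for gcode in np.unique(obs.ref[idx_obs][rows].astype(np.intp)):
                gk = (key, int(gcode))
                if gk not in key_codes:
                    key_codes[gk] = next_code
                    members = np.flatnonzero(ctrl_ref == gcode)
                    if members.size == 0:
                        raise ValueError(
                            f"no control columns with reference {NUCLEOTIDES[gcode]}"
                        )
                    ctrl_depths[next_code] = depth_profile(
                        controls.states[members], cdist, _set_mask(key)
                    )
                    ctrl_members[next_code] = members
                    next_code += 1
                sub = rows[obs.ref[idx_obs][rows] == gcode]
                obs_groups[sub] = key_codes[gk]

    obs_mean = float(obs_depth.mean())
    w = {g: float((obs_groups == g).mean()) for g in np.unique(obs_groups)}
    gmeans = {g: float(ctrl_depths[g].mean()) for g in w}
    exp_mean = sum(w[g] * gmeans[g] for g in w)
    if exp_mean == 0:
        raise ValueError("neutral expectation is zero; contrast undefined")
    c = (obs_mean - exp_mean) / exp_mean

    # joint bootstrap over observed and control columns
    rng = np.random.default_rng(seed)
    n_o = idx_obs.size
    cs = np.empty(B)
    group_list = sorted(w)
    pos = 0
    while pos < B:
        b = min(chunk, B - pos)
        io = rng.integers(0, n_o, size=(b, n_o))
        d = obs_depth[io]
        gb = obs_groups[io]
        obs_b = d.mean(axis=1)
        exp_b = np.zeros(b)
        for g in group_list:
            wt = (gb == g).mean(axis=1)
            pool = ctrl_depths[g]
            ic = rng.integers(0, pool.size, size=(b, pool.size))
            exp_b += wt * pool[ic].mean(axis=1)
        cs[pos : pos + b] = (obs_b - exp_b) / np.where(exp_b == 0, np.nan, exp_b)
        pos += b
    lo, hi = np.nanpercentile(cs, [2.5, 97.5])
    if lo == hi:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
    n_ctrl = sum(ctrl_depths[g].size for g in group_list)
    return ConservationResult(
        selector=selector,
        obs=obs_mean,
        exp=exp_mean,
        c=c,
        ci_low=float(lo),
        ci_high=float(hi),
        n_obs=int(n_o),
        n_ctrl=int(n_ctrl),
    )


def load_panel(
    alignment,
    tree,
    reference: str,
    offsets=None,
    site_type: str = "panel",
) -> PanelColumns:
    """Build PanelColumns from an aligned FASTA and a Newick tree.

    Species are ordered by path length (taken as Ks) from the reference
    taxon; every alignment column becomes one panel column.  ``offsets``
    optionally assigns a splice-site offset to each column (defaults to 0,
    suitable for neutral control panels).
    """
    from Bio import AlignIO, Phylo

    aln = AlignIO.read(str(alignment), "fasta")
    phylo = Phylo.read(str(tree), "newick")
    rows = {rec.id: str(rec.seq).upper() for rec in aln}
    if reference not in rows:
        raise ValueError(f"reference {reference!r} absent from the alignment")
    dists = {
        leaf.name: float(phylo.distance(reference, leaf.name))
        for leaf in phylo.get_terminals()
        if leaf.name != reference and leaf.name in rows
    }
    if not dists:
        raise ValueError("no non-reference species shared by tree and alignment")
    species = sorted(dists, key=lambda s: (dists[s], s))
    n_cols = aln.get_alignment_length()

    def codes(seq: str) -> np.ndarray:
        return np.array([NUC_INDEX.get(c, -1) for c in seq], dtype=np.int8)

    ref_codes = codes(rows[reference])
    states = np.stack([codes(rows[s]) for s in species], axis=1)
    off = (
        np.zeros(n_cols, dtype=np.int64)
        if offsets is None
        else np.asarray(offsets, dtype=np.int64)
    )
    if off.size != n_cols:
        raise ValueError("offsets must match the alignment length")
    return PanelColumns(
        site_type=site_type,
        offsets=off,
        site_index=np.arange(n_cols),
        ref=ref_codes,
        states=states,
        distances=np.array([dists[s] for s in species]),
    )


def bootstrap_ci(
    columns,
    statistic: Callable,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 interval of a statistic over column resamples.

    ``columns`` is indexed along its first axis; the statistic is evaluated
    on each resample drawn with replacement.  Deterministic for fixed seed.
    """
    arr = np.asarray(columns)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("bootstrap requires at least two columns")
    rng = np.random.default_rng(seed)
    vals = np.array(
        [statistic(arr[rng.integers(0, n, size=n)]) for _ in range(B)], dtype=float
    )
    lo, hi = np.percentile(vals, [2.5, 97.5])
    if lo == hi:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
    return float(lo), float(hi)
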