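"""Origination-fixation simulator for splice-site triplet alignments.

The simulator works at the substitution level (weak-mutation regime): each
position is monomorphic, and the rate of replacing allele Z by allele X is

    rate(Z -> X) = mu[Z, X] * r(f[X] - f[Z]),

where ``mu`` holds per-Ks mutation rates, ``f`` is the vector of scaled
fitnesses (4*Ne*s units) and r is the Kimura fixation ratio
S / (1 - exp(-S)).  Branch transition matrices are matrix exponentials of
the resulting rate matrix, ancestral states are drawn from its stationary
distribution, and the three extant species (reference, sister, outgroup)
descend from a common ancestor on the topology ((ref, sister), outgroup).

Per splice site, every position carries a class-level fitness landscape in
which the consensus (Cn) alleles share the maximal fitness and every
nonconsensus (Nc) allele sits ``S`` below it (S < 0 means Cn is favored).
Optionally, a fraction of sites has the fitness maximum reassigned to one
uniformly chosen Nc allele, producing site-specific preference for a
resident Nc nucleotide.  The canonical GT/AG dinucleotides are immutable.

Matched neutral controls (intronic-like and fourfold-degenerate-like pools)
are generated under the same mutation process with all fitnesses equal, and
carry synthetic per-position neutrality scores so that downstream score
filters can be exercised.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .selection import fixation_ratio
from .sites import (
    ACCEPTOR,
    DONOR,
    NUC_INDEX,
    NUCLEOTIDES,
    ConsensusTable,
    Role,
    SpliceSiteRecord,
    invariant_bases,
    position_role,
    site_offsets,
)

__all__ = [
    "SimParams",
    "TripletEnsemble",
    "ControlBlock",
    "PanelColumns",
    "PanelEnsemble",
    "hky_mutation_matrix",
    "normalize_mutation_matrix",
    "rate_matrix",
    "stationary_frequencies",
    "substitution_matrix",
    "simulate_triplet_ensemble",
    "simulate_panel",
]

#: root-to-species Ks ladder emulating a deep multispecies panel
DEFAULT_PANEL_DISTANCES: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.geomspace(0.05, 4.0, 16), 4)
)


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic named child stream of the master seed."""
    ints = [int(seed) & 0x7FFFFFFF]
    ints += [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _fitness_vector(selection) -> np.ndarray:
    if selection is None:
        return np.zeros(4)
    if isinstance(selection, Mapping):
        f = np.zeros(4)
        for nuc, val in selection.items():
            f[NUC_INDEX[str(nuc).upper()]] = float(val)
        return f
    f = np.asarray(selection, dtype=float)
    if f.shape != (4,):
        raise ValueError("selection must map the four alleles to fitnesses")
    return f


def _check_connected(mu: np.ndarray) -> None:
    adj = (mu > 0).astype(int)
    np.fill_diagonal(adj, 1)
    reach = np.linalg.matrix_power(adj, 3)
    if not np.all(reach > 0):
        raise ValueError("mutation matrix is absorbing or disconnected")


def _mutation_only_stationary(mu: np.ndarray) -> np.ndarray:
    q = mu.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    a = np.vstack([q.T, np.ones(4)])
    b = np.zeros(5)
    b[4] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def normalize_mutation_matrix(mu: np.ndarray) -> np.ndarray:
    """Scale mutation rates so one Ks unit = one expected neutral substitution.

    The expected neutral substitution rate is the mutation-only stationary
    distribution contracted with the per-allele total exit rates.
    """
    mu = np.array(mu, dtype=float)
    if mu.shape != (4, 4):
        raise ValueError("mutation matrix must be 4x4")
    np.fill_diagonal(mu, 0.0)
    if np.any(mu < 0):
        raise ValueError("mutation rates must be non-negative")
    _check_connected(mu)
    pi0 = _mutation_only_stationary(mu)
    scale = float(pi0 @ mu.sum(axis=1))
    if scale <= 0:
        raise ValueError("mutation matrix has zero total rate")
    return mu / scale


def hky_mutation_matrix(kappa: float = 2.0) -> np.ndarray:
    """Symmetric HKY-like mutation rates with transition/transversion ratio
    kappa, normalized to one expected neutral substitution per Ks unit."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    mu = np.ones((4, 4))
    a, c, g, t = (NUC_INDEX[x] for x in "ACGT")
    for i, j in ((a, g), (g, a), (c, t), (t, c)):
        mu[i, j] = kappa
    np.fill_diagonal(mu, 0.0)
    return normalize_mutation_matrix(mu)


def rate_matrix(mutation_matrix: np.ndarray, selection) -> np.ndarray:
    """Substitution rate matrix: mu[Z, X] * r(f[X] - f[Z]), diagonal = -rowsum."""
    mu = np.asarray(mutation_matrix, dtype=float)
    if np.any(mu[~np.eye(4, dtype=bool)] < 0):
        raise ValueError("mutation rates must be non-negative")
    f = _fitness_vector(selection)
    if not np.all(np.isfinite(f)):
        raise ValueError("selection values must be finite")
    q = mu * fixation_ratio(f[None, :] - f[:, None])
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_frequencies(mutation_matrix: np.ndarray, selection=None) -> np.ndarray:
    """Equilibrium allele frequencies of the origination-fixation process.

    Solves pi Q = 0 with sum(pi) = 1.  For a symmetric mutation matrix the
    result satisfies detailed balance with pi(X)/pi(Z) = exp(f[X] - f[Z]).
    """
    mu = np.asarray(mutation_matrix, dtype=float)
    _check_connected(np.where(np.eye(4, dtype=bool), 0.0, mu))
    q = rate_matrix(mu, selection)
    a = np.vstack([q.T, np.ones(4)])
    b = np.zeros(5)
    b[4] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-9):
        raise ValueError("no valid stationary distribution (reducible process)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def substitution_matrix(
    branch_length: float, mutation_matrix: np.ndarray, selection=None
) -> np.ndarray:
    """4x4 transition probabilities over a branch of the given Ks length."""
    t = float(branch_length)
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(4)
    p = expm(rate_matrix(mutation_matrix, selection) * t)
    p = np.clip(p, 0.0, 1.0)
    return p / p.sum(axis=1, keepdims=True)


def _draw(pi: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    # scalar thresholds beat searchsorted for a 4-state alphabet; float32
    # uniforms halve the memory traffic at no practical cost to the model
    cdf = np.cumsum(pi).astype(np.float32)
    cdf[-1] = 1.0
    u = rng.random(size, dtype=np.float32)
    out = (u > cdf[0]).astype(np.int8)
    out += u > cdf[1]
    out += u > cdf[2]
    return out


def _evolve(states: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(P, axis=1).astype(np.float32)
    cdf[:, -1] = 1.0
    u = rng.random(states.shape[0], dtype=np.float32)
    out = (u > cdf[states, 0]).astype(np.int8)
    out += u > cdf[states, 1]
    out += u > cdf[states, 2]
    return out


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------


@dataclass
class SimParams:
    """Study conditions for one synthetic splice-site ensemble.

    S_profile gives the scaled fitness (4*Ne*s) of each Nc allele relative
    to the Cn alleles at that offset; a negative value means Cn is favored.
    A scalar applies to every non-invariant position with a defined Cn set.
    ``t_sister`` and ``t_outgroup`` are reference-to-sister and
    reference-to-outgroup Ks distances; the reference/sister split is placed
    halfway along the sister path.  ``n_controls`` is the size of each
    neutral control pool (intronic-like and fourfold-like); the default,
    100x the site count, keeps the neutral-rate sampling error well below
    the splice-site sampling error so that control error can be neglected
    in downstream confidence intervals.
    """

    n_sites: int
    site_type: str = DONOR
    S_profile: float | Mapping[int, float] = -2.0
    site_specific_fraction: float = 0.0
    site_specific_S: float = 2.0
    consensus: ConsensusTable = field(default_factory=ConsensusTable.default)
    mutation_matrix: np.ndarray | None = None
    kappa: float = 2.0
    t_sister: float = 0.06
    t_outgroup: float = 0.13
    panel_distances: tuple[float, ...] = DEFAULT_PANEL_DISTANCES
    n_controls: int | None = None
    control_score_sd: float = 0.9
    cpg_rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if self.site_type not in (DONOR, ACCEPTOR):
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not 0.0 <= self.site_specific_fraction <= 1.0:
            raise ValueError("site_specific_fraction must lie in [0, 1]")
        if self.t_sister < 0 or self.t_outgroup < 0:
            raise ValueError("branch lengths must be non-negative")
        if self.t_outgroup < self.t_sister / 2.0:
            raise ValueError(
                "t_outgroup must be at least half of t_sister (the outgroup "
                "diverges before the reference/sister split)"
            )
        if any(d < 0 for d in self.panel_distances):
            raise ValueError("panel distances must be non-negative")
        if self.cpg_rate_multiplier <= 0:
            raise ValueError("cpg_rate_multiplier must be positive")
        if self.mutation_matrix is None:
            self.mutation_matrix = hky_mutation_matrix(self.kappa)
        else:
            self.mutation_matrix = normalize_mutation_matrix(self.mutation_matrix)

    def S_at(self, offset: int) -> float:
        role = position_role(self.site_type, offset)
        if role in (Role.INVARIANT, Role.NO_CONSENSUS):
            return 0.0
        if self.consensus.cn(self.site_type, offset) is None:
            return 0.0
        if isinstance(self.S_profile, Mapping):
            return float(self.S_profile.get(offset, 0.0))
        return float(self.S_profile)

    @property
    def effective_n_controls(self) -> int:
        return self.n_controls if self.n_controls is not None else 100 * self.n_sites


@dataclass
class ControlBlock:
    """One neutral control pool: triplet states plus auxiliary truth.

    ``prev``/``next_`` are the true ancestral neighbors of each control
    position, carried so that CpG-context exclusion can be exercised on
    controls; ``score`` is a synthetic per-position neutrality score
    (phyloP-like, centered on zero because every control evolves neutrally).
    """

    anc_true: np.ndarray
    prev: np.ndarray
    next_: np.ndarray
    ref: np.ndarray
    sister: np.ndarray
    outgroup: np.ndarray
    score: np.ndarray


@dataclass
class TripletEnsemble:
    """Simulated reference/sister/outgroup splice-site alignments."""

    site_type: str
    offsets: tuple[int, ...]
    ref: np.ndarray  # (n_sites, n_positions) int8 codes 0..3
    sister: np.ndarray
    outgroup: np.ndarray
    anc_true: np.ndarray  # true ancestor of the (ref, sister) clade
    truth_S: np.ndarray  # (n_sites, n_positions) class-level S, NaN at invariant
    favored: np.ndarray  # (n_sites, n_positions) favored Nc code, -1 if class-level
    consensus: ConsensusTable
    controls: dict[str, ControlBlock]
    params: SimParams

    @property
    def n_sites(self) -> int:
        return self.ref.shape[0]

    def sequences(self, which: str) -> list[str]:
        arr = getattr(self, which)
        lut = np.array(list(NUCLEOTIDES))
        return ["".join(lut[row]) for row in arr]

    def to_records(self) -> list[SpliceSiteRecord]:
        refs = self.sequences("ref")
        sis = self.sequences("sister")
        out = self.sequences("outgroup")
        return [
            SpliceSiteRecord(
                site_id=f"sim_{self.site_type}_{i}",
                site_type=self.site_type,
                seq_by_species={"ref": refs[i], "sister": sis[i], "outgroup": out[i]},
            )
            for i in range(self.n_sites)
        ]


@dataclass
class PanelColumns:
    """Multispecies alignment columns at increasing distance from the reference."""

    site_type: str
    offsets: np.ndarray  # (n_cols,) offset of each column
    site_index: np.ndarray  # (n_cols,)
    ref: np.ndarray  # (n_cols,) reference nucleotide codes
    states: np.ndarray  # (n_cols, n_species) codes, ordered by distance
    distances: np.ndarray  # (n_species,) non-decreasing Ks from the reference
    favored: np.ndarray | None = None  # (n_cols,) favored Nc code or -1


@dataclass
class PanelEnsemble:
    sites: PanelColumns
    controls: PanelColumns


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _position_groups(params: SimParams, offset: int, favored_col: np.ndarray):
    """Yield (mask, fitness_vector, group_key) for one position.

    Group 0 is the class-level landscape; each favored Nc allele at
    site-specific sites forms its own group with the fitness maximum moved
    to that allele.
    """
    cn = params.consensus.cn(params.site_type, offset)
    S = params.S_at(offset)
    f0 = np.zeros(4)
    if cn is not None and S != 0.0:
        for nuc in NUCLEOTIDES:
            if nuc not in cn:
                f0[NUC_INDEX[nuc]] = S
    base_mask = favored_col < 0
    if base_mask.any():
        yield base_mask, f0, "class"
    for code in np.unique(favored_col[favored_col >= 0]):
        f = np.zeros(4)
        f[code] = abs(params.site_specific_S)
        yield favored_col == code, f, f"fav{code}"


def _branch_lengths(params: SimParams) -> tuple[float, float, float]:
    t_ref = params.t_sister / 2.0
    return t_ref, t_ref, params.t_outgroup - t_ref


def _cpg_mu(mu: np.ndarray, multiplier: float) -> np.ndarray:
    """Mutation matrix with C->T and G->A inflated (CpG hypermutability)."""
    out = mu.copy()
    c, t, g, a = NUC_INDEX["C"], NUC_INDEX["T"], NUC_INDEX["G"], NUC_INDEX["A"]
    out[c, t] *= multiplier
    out[g, a] *= multiplier
    return out


def _cpg_mask(anc: np.ndarray) -> np.ndarray:
    """Positions that are part of a CG dinucleotide in the ancestral sequence."""
    c, g = NUC_INDEX["C"], NUC_INDEX["G"]
    mask = np.zeros(anc.shape, dtype=bool)
    is_c = anc == c
    is_g = anc == g
    mask[:, :-1] |= is_c[:, :-1] & is_g[:, 1:]
    mask[:, 1:] |= is_g[:, 1:] & is_c[:, :-1]
    return mask


def simulate_triplet_ensemble(params: SimParams) -> TripletEnsemble:
    """Simulate an ensemble of splice-site triplet alignments plus controls.

    Deterministic for a fixed SimParams (including seed): every random draw
    comes from a named child stream of the master seed.
    """
    offsets = site_offsets(params.site_type)
    n, n_pos = params.n_sites, len(offsets)
    mu = params.mutation_matrix
    seed = params.seed
    t_ref, t_sis, t_out = _branch_lengths(params)
    inv = invariant_bases(params.site_type)

    # site-specific Nc preference assignment
    favored = np.full((n, n_pos), -1, dtype=np.int8)
    n_special = int(round(params.site_specific_fraction * n))
    if n_special:
        rng = _rng(seed, "site_specific")
        rows = rng.choice(n, size=n_special, replace=False)
        for j, off in enumerate(offsets):
            cn = params.consensus.cn(params.site_type, off)
            if cn is None:
                continue
            nc_codes = np.array(
                [NUC_INDEX[x] for x in NUCLEOTIDES if x not in cn], dtype=np.int8
            )
            favored[rows, j] = rng.choice(nc_codes, size=n_special)

    anc = np.empty((n, n_pos), dtype=np.int8)
    ref = np.empty_like(anc)
    sister = np.empty_like(anc)
    outgroup = np.empty_like(anc)
    truth_S = np.zeros((n, n_pos))

    for j, off in enumerate(offsets):
        role = position_role(params.site_type, off)
        if role is Role.INVARIANT:
            code = NUC_INDEX[inv[off]]
            anc[:, j] = ref[:, j] = sister[:, j] = outgroup[:, j] = code
            truth_S[:, j] = np.nan
            continue
        S = params.S_at(off)
        for mask, f, gkey in _position_groups(params, off, favored[:, j]):
            idx = np.flatnonzero(mask)
            pi = stationary_frequencies(mu, f)
            p_ref = substitution_matrix(t_ref, mu, f)
            p_sis = substitution_matrix(t_sis, mu, f)
            p_out = substitution_matrix(t_out, mu, f)
            a = _draw(pi, idx.size, _rng(seed, "anc", off, gkey))
            anc[idx, j] = a
            ref[idx, j] = _evolve(a, p_ref, _rng(seed, "ref", off, gkey))
            sister[idx, j] = _evolve(a, p_sis, _rng(seed, "sister", off, gkey))
            outgroup[idx, j] = _evolve(a, p_out, _rng(seed, "outgroup", off, gkey))
        truth_S[:, j] = S
        truth_S[favored[:, j] >= 0, j] = abs(params.site_specific_S)

    if params.cpg_rate_multiplier != 1.0:
        mu_cpg = _cpg_mu(mu, params.cpg_rate_multiplier)
        cpg = _cpg_mask(anc)
        for j, off in enumerate(offsets):
            if position_role(params.site_type, off) is Role.INVARIANT:
                continue
            col = np.flatnonzero(cpg[:, j])
            if col.size == 0:
                continue
            for mask, f, gkey in _position_groups(params, off, favored[:, j]):
                idx = col[mask[col]]
                if idx.size == 0:
                    continue
                a = anc[idx, j]
                for name, t, arr in (
                    ("ref", t_ref, ref),
                    ("sister", t_sis, sister),
                    ("outgroup", t_out, outgroup),
                ):
                    p = substitution_matrix(t, mu_cpg, f)
                    arr[idx, j] = _evolve(a, p, _rng(seed, "cpg", name, off, gkey))

    controls = {
        prov: _simulate_control_block(params, prov)
        for prov in ("intronic-control", "fourfold-control")
    }

    ens = TripletEnsemble(
        site_type=params.site_type,
        offsets=offsets,
        ref=ref,
        sister=sister,
        outgroup=outgroup,
        anc_true=anc,
        truth_S=truth_S,
        favored=favored,
        consensus=params.consensus,
        controls=controls,
        params=params,
    )
    # canonical dinucleotides are immutable by construction; verify anyway
    for off, base in inv.items():
        j = offsets.index(off)
        code = NUC_INDEX[base]
        assert (ref[:, j] == code).all() and (sister[:, j] == code).all()
    return ens


def _simulate_control_block(params: SimParams, provenance: str) -> ControlBlock:
    m = params.effective_n_controls
    mu = params.mutation_matrix
    seed = params.seed
    t_ref, t_sis, t_out = _branch_lengths(params)
    pi0 = stationary_frequencies(mu, None)
    anc = _draw(pi0, m, _rng(seed, "ctrl-anc", provenance))
    prev = _draw(pi0, m, _rng(seed, "ctrl-prev", provenance))
    next_ = _draw(pi0, m, _rng(seed, "ctrl-next", provenance))
    p_ref = substitution_matrix(t_ref, mu, None)
    p_sis = substitution_matrix(t_sis, mu, None)
    p_out = substitution_matrix(t_out, mu, None)
    ref = _evolve(anc, p_ref, _rng(seed, "ctrl-ref", provenance))
    sister = _evolve(anc, p_sis, _rng(seed, "ctrl-sister", provenance))
    outgroup = _evolve(anc, p_out, _rng(seed, "ctrl-outgroup", provenance))
    if params.cpg_rate_multiplier != 1.0:
        c, g = NUC_INDEX["C"], NUC_INDEX["G"]
        mask = ((anc == c) & (next_ == g)) | ((anc == g) & (prev == c))
        idx = np.flatnonzero(mask)
        if idx.size:
            mu_cpg = _cpg_mu(mu, params.cpg_rate_multiplier)
            for name, t, arr in (
                ("ref", t_ref, ref),
                ("sister", t_sis, sister),
                ("outgroup", t_out, outgroup),
            ):
                p = substitution_matrix(t, mu_cpg, None)
                arr[idx] = _evolve(anc[idx], p, _rng(seed, "ctrl-cpg", name, provenance))
    score = _rng(seed, "ctrl-score", provenance).normal(
        0.0, params.control_score_sd, m
    )
    return ControlBlock(
        anc_true=anc,
        prev=prev,
        next_=next_,
        ref=ref,
        sister=sister,
        outgroup=outgroup,
        score=score,
    )


def simulate_panel(
    params: SimParams,
    distances: Sequence[float] | None = None,
    ensemble: TripletEnsemble | None = None,
    n_control_columns: int | None = None,
) -> PanelEnsemble:
    """Simulate multispecies panel columns for splice sites and controls.

    Species sit on a ladder at the given non-decreasing root-to-species Ks
    distances from the reference: the nearest species evolves from the
    extant reference state over the first distance, and each further species
    evolves from its predecessor over the distance increment, so states are
    correlated through shared path length.  Because the process is at
    stationarity and reversible, conditioning on the extant reference state
    is exact.  Control columns evolve the same way with all fitnesses equal.
    """
    dist = np.asarray(
        params.panel_distances if distances is None else list(distances), dtype=float
    )
    if dist.size == 0:
        raise ValueError("panel distance list must not be empty")
    if np.any(np.diff(dist) < 0):
        raise ValueError("panel distances must be non-decreasing")
    if np.any(dist < 0):
        raise ValueError("panel distances must be non-negative")
    if ensemble is None:
        ensemble = simulate_triplet_ensemble(params)

    offsets = ensemble.offsets
    mu = params.mutation_matrix
    seed = params.seed
    n = ensemble.n_sites
    keep = [
        j
        for j, off in enumerate(offsets)
        if position_role(params.site_type, off) is not Role.INVARIANT
    ]
    n_cols = n * len(keep)
    col_off = np.empty(n_cols, dtype=np.int64)
    col_site = np.empty(n_cols, dtype=np.int64)
    col_ref = np.empty(n_cols, dtype=np.int8)
    col_fav = np.empty(n_cols, dtype=np.int8)
    states = np.empty((n_cols, dist.size), dtype=np.int8)

    pos = 0
    increments = np.diff(np.concatenate([[0.0], dist]))
    for j in keep:
        off = offsets[j]
        sl = slice(pos, pos + n)
        col_off[sl] = off
        col_site[sl] = np.arange(n)
        col_ref[sl] = ensemble.ref[:, j]
        col_fav[sl] = ensemble.favored[:, j]
        for mask, f, gkey in _position_groups(params, off, ensemble.favored[:, j]):
            idx = np.flatnonzero(mask)
            cur = ensemble.ref[idx, j]
            for k, d in enumerate(increments):
                p = substitution_matrix(d, mu, f)
                cur = _evolve(cur, p, _rng(seed, "panel", off, gkey, k))
                states[pos + idx, k] = cur
        pos += n

    m = n_cols if n_control_columns is None else int(n_control_columns)
    pi0 = stationary_frequencies(mu, None)
    ctrl_ref = _draw(pi0, m, _rng(seed, "panel-ctrl-ref"))
    ctrl_states = np.empty((m, dist.size), dtype=np.int8)
    cur = ctrl_ref
    p_neutral = [substitution_matrix(d, mu, None) for d in increments]
    for k, p in enumerate(p_neutral):
        cur = _evolve(cur, p, _rng(seed, "panel-ctrl", k))
        ctrl_states[:, k] = cur

    return PanelEnsemble(
        sites=PanelColumns(
            site_type=params.site_type,
            offsets=col_off,
            site_index=col_site,
            ref=col_ref,
            states=states,
            distances=dist,
            favored=col_fav,
        ),
        controls=PanelColumns(
            site_type=params.site_type,
            offsets=np.zeros(m, dtype=np.int64),
            site_index=np.arange(m),
            ref=ctrl_ref,
            states=ctrl_states,
            distances=dist,
            favored=None,
        ),
    )


# ---------------------------------------------------------------------------
# text output
# ---------------------------------------------------------------------------


def write_fasta(ensemble: TripletEnsemble, directory) -> None:
    """Write one aligned FASTA per species (records share the site ids)."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for which in ("ref", "sister", "outgroup"):
        seqs = ensemble.sequences(which)
        recs = [
            SeqRecord(Seq(s), id=f"sim_{ensemble.site_type}_{i}", description="")
            for i, s in enumerate(seqs)
        ]
        SeqIO.write(recs, directory / f"{which}.fa", "fasta")


def control_table(ensemble: TripletEnsemble):
    """Long-format control table (provenance, triplet states, score, context)."""
    import pandas as pd

    lut = np.array(list(NUCLEOTIDES))
    frames = []
    for prov, block in ensemble.controls.items():
        frames.append(
            pd.DataFrame(
                {
                    "provenance": prov,
                    "ref": lut[block.ref],
                    "sister": lut[block.sister],
                    "outgroup": lut[block.outgroup],
                    "prev": lut[block.prev],
                    "next": lut[block.next_],
                    "score": block.score,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
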