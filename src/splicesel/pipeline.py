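"""End-to-end orchestration: simulate/extract -> reconstruct -> count ->
infer -> conserve -> report.

Every stage reads and writes plain TSV tables so stages are independently
testable; a run manifest (config hash, seed, package versions) makes runs
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ancestral import (
    ControlObservations,
    SubstitutionCounts,
    control_observations_from_frame,
    count_substitutions,
    reconstruct_controls,
)
from .conservation import conservation_contrast
from .selection import (
    LoadSummary,
    drift_load,
    estimate_selection,
    per_locus_s,
)
from .simulate import (
    DEFAULT_PANEL_DISTANCES,
    SimParams,
    TripletEnsemble,
    simulate_panel,
    simulate_triplet_ensemble,
)
from .sites import (
    ACCEPTOR,
    DONOR,
    ConsensusTable,
    Role,
    assign_strength_classes,
    position_role,
    read_site_table,
    site_offsets,
)
from .substitution import (
    CN_TO_NC,
    NC_TO_CN,
    class_frequency,
    expected_frequency,
    neutral_rates,
    offset_table,
    pooled_class_counts,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "DataError", "run_pipeline", "stratify"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class DataError(ValueError):
    """Invalid or missing input data."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-serializable).

    All analysis thresholds default to the study values: neutrality-score
    threshold 0.6 (retaining |score| below it), alpha 0.05, 1000 bootstrap
    trials, strength tertiles.
    """

    mode: str = "synthetic"
    seed: int | None = 0
    site_types: tuple[str, ...] = (DONOR, ACCEPTOR)
    # synthetic-mode generator settings
    n_sites: int = 20000
    S: float = -2.0
    site_specific_fraction: float = 0.0
    site_specific_S: float = 2.0
    kappa: float = 2.0
    t_sister: float = 0.06
    t_outgroup: float = 0.13
    n_controls: int | None = None
    cpg_rate_multiplier: float = 1.0
    panel_sites: int = 2000
    panel_distances: tuple[float, ...] = DEFAULT_PANEL_DISTANCES
    # analysis options
    exclude_cpg: bool = False
    polarization: str = "strict"
    score_threshold: float = 0.6
    keep_below: bool = True
    alpha: float = 0.05
    bootstrap_B: int = 1000
    Ne: float = 1e4
    load_n_ss: float | None = None
    stratifiers: tuple[str, ...] = ()
    run_conservation: bool = True
    # real-mode inputs
    site_table: str | None = None
    control_table: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ConfigError("seed is mandatory in synthetic mode")
        if self.mode == "real":
            for path in (self.site_table, self.control_table):
                if path is None:
                    raise ConfigError(
                        "real mode requires site_table and control_table paths"
                    )
                if not Path(path).exists():
                    raise ConfigError(f"input path does not exist: {path}")
        for st in self.site_types:
            if st not in (DONOR, ACCEPTOR):
                raise ConfigError(f"unknown site type {st!r}")
        if self.polarization not in ("strict", "parsimony"):
            raise ConfigError(f"unknown polarization {self.polarization!r}")
        known = {"coding_class", "splicing_class", "strength_class"}
        for s in self.stratifiers:
            if s not in known:
                raise ConfigError(f"unknown stratifier {s!r} (choose from {known})")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("site_types", "stratifiers", "panel_distances"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:  # wrong types
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("site_types", "stratifiers", "panel_distances"):
            d[key] = list(d[key])
        return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def stratify(
    table: pd.DataFrame,
    by: str,
    covariate: pd.Series | None = None,
    n_bins: int = 3,
    labels: Sequence[str] | None = None,
) -> pd.Series:
    """Assign stratum labels to records.

    If ``by`` names a categorical column of ``table`` its values are the
    strata.  Otherwise ``covariate`` must supply a numeric value per record
    (aligned on index); records are ranked with a stable sort (ties broken
    by input order, hence by site_id order for site-id-sorted tables) and
    split into ``n_bins`` near-equal quantile strata.  Records with a
    missing covariate are dropped with a logged warning; a constant
    covariate yields a single stratum with a warning.
    """
    if covariate is None:
        if by not in table.columns:
            raise DataError(f"stratifier {by!r} is not a column and no covariate given")
        return table[by].astype(str)
    cov = pd.Series(covariate).reindex(table.index)
    missing = cov.isna()
    if missing.any():
        log.warning("dropping %d records with missing covariate %r", missing.sum(), by)
    if labels is None:
        labels = (
            ["low", "high"]
            if n_bins == 2
            else [f"q{i + 1}" for i in range(n_bins)]
            if n_bins != 3
            else ["low", "middle", "high"]
        )
    out = pd.Series(index=table.index, dtype=object)
    vals = cov[~missing]
    if vals.nunique() <= 1:
        log.warning("constant covariate %r: single stratum", by)
        out[~missing] = labels[0]
        return out
    classes, _ = assign_strength_classes(vals.to_numpy(), labels=tuple(labels))
    out[~missing] = classes
    return out


def _selection_table(
    counts: SubstitutionCounts,
    neutral,
    consensus: ConsensusTable,
    alpha: float,
) -> pd.DataFrame:
    site_type = counts.site_type
    rows = []
    for off in consensus.scored_offsets(site_type):
        comp = counts.composition(off)
        for direction in (CN_TO_NC, NC_TO_CN):
            est = class_frequency(counts, consensus, site_type, off, direction, alpha)
            if est.n == 0:
                continue
            q_exp, _, _ = expected_frequency(
                comp, neutral, consensus, site_type, off, direction, n_obs=est.n
            )
            sel = estimate_selection(est, q_exp)
            rows.append(
                {
                    "site_type": site_type,
                    "offset": off,
                    "direction": direction,
                    "role": position_role(site_type, off).value,
                    "q": est.q,
                    "q_exp": q_exp,
                    "r": sel.r,
                    "S_hat": sel.S_hat,
                    "S_low": sel.S_low,
                    "S_high": sel.S_high,
                }
            )
    for direction in (CN_TO_NC, NC_TO_CN):
        pooled, q_exp = pooled_class_counts(counts, neutral, consensus, direction, alpha)
        sel = estimate_selection(pooled, q_exp)
        rows.append(
            {
                "site_type": site_type,
                "offset": "pooled",
                "direction": direction,
                "role": "pooled",
                "q": pooled.q,
                "q_exp": q_exp,
                "r": sel.r,
                "S_hat": sel.S_hat,
                "S_low": sel.S_low,
                "S_high": sel.S_high,
            }
        )
    return pd.DataFrame(rows)


def _conservation_table(
    panel, consensus: ConsensusTable, site_type: str, B: int, seed: int
) -> pd.DataFrame:
    rows = []
    for class_name in ("Cn", "Nc"):
        class_sets = {}
        for off in consensus.scored_offsets(site_type):
            cn = consensus.cn(site_type, off)
            class_sets[off] = cn if class_name == "Cn" else consensus.nc(site_type, off)
        for selector in ("nuc", "set"):
            res = conservation_contrast(
                panel.sites,
                panel.controls,
                selector,
                class_sets,
                B=B,
                seed=seed,
            )
            rows.append(
                {
                    "site_type": site_type,
                    "class": class_name,
                    "selector": selector,
                    "obs": res.obs,
                    "exp": res.exp,
                    "c": res.c,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_obs": res.n_obs,
                    "n_ctrl": res.n_ctrl,
                }
            )
    return pd.DataFrame(rows)


def _nc_stats(ref: np.ndarray, offsets, site_type: str, consensus: ConsensusTable):
    """Mean Nc count per site and Cn fraction over scored offsets."""
    scored = consensus.scored_offsets(site_type)
    cols = [list(offsets).index(o) for o in scored]
    mask = consensus.cn_mask(site_type)[cols]  # (n_scored, 4)
    is_cn = np.take_along_axis(
        mask.T[None, :, :].repeat(ref.shape[0], axis=0),
        ref[:, cols][:, None, :].astype(np.intp),
        axis=1,
    )[:, 0, :]
    nc_per_site = (~is_cn).sum(axis=1)
    mean_nc = float(nc_per_site.mean())
    cn_fraction = 1.0 - mean_nc / len(scored)
    return mean_nc, cn_fraction


def _write(df: pd.DataFrame, path: Path, meta: Mapping[str, str] | None = None):
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _sim_params(config: RunConfig, site_type: str, n_sites: int | None = None):
    return SimParams(
        n_sites=n_sites or config.n_sites,
        site_type=site_type,
        S_profile=config.S,
        site_specific_fraction=config.site_specific_fraction,
        site_specific_S=config.site_specific_S,
        kappa=config.kappa,
        t_sister=config.t_sister,
        t_outgroup=config.t_outgroup,
        panel_distances=config.panel_distances,
        n_controls=config.n_controls,
        cpg_rate_multiplier=config.cpg_rate_multiplier,
        seed=int(config.seed or 0),
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all stages for every configured site type; write TSVs + manifest.

    Returns a dict with the per-site-type tables and load summaries.
    Re-running with an identical config reproduces identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consensus = ConsensusTable.default()
    meta = {"config_hash": config_hash(config), "splicesel": __version__}
    results: dict = {"config": config, "manifest": None}

    for site_type in config.site_types:
        stage = f"{site_type} ensemble"
        try:
            if config.mode == "synthetic":
                params = _sim_params(config, site_type)
                ens = simulate_triplet_ensemble(params)
                counts = count_substitutions(
                    ens,
                    consensus,
                    exclude_cpg=config.exclude_cpg,
                    polarization=config.polarization,
                )
                ctrl_obs = reconstruct_controls(
                    ens.controls, polarization=config.polarization
                )
                ref_codes, offsets = ens.ref, ens.offsets
                records_df = None
            else:
                records = [
                    r
                    for r in read_site_table(config.site_table)
                    if r.site_type == site_type
                ]
                if not records:
                    log.warning("no %s records in site table; skipped", site_type)
                    continue
                counts = count_substitutions(
                    records,
                    consensus,
                    exclude_cpg=config.exclude_cpg,
                    polarization=config.polarization,
                )
                ctrl_obs = control_observations_from_frame(
                    pd.read_csv(config.control_table, sep="\t", comment="#"),
                    polarization=config.polarization,
                )
                ens = None
                offsets = site_offsets(site_type)
                from .ancestral import _encode  # reuse the symbol encoder

                ref_codes = np.array(
                    [[_encode(c) for c in r.seq_by_species["ref"]] for r in records],
                    dtype=np.int8,
                )
        except (ValueError, OSError) as exc:
            raise DataError(f"stage '{stage}' failed: {exc}") from exc

        stage = f"{site_type} inference"
        try:
            neutral = neutral_rates(
                ctrl_obs,
                score_threshold=config.score_threshold,
                keep_below=config.keep_below,
                exclude_cpg=config.exclude_cpg,
            )
            rates = offset_table(counts, neutral, consensus, alpha=config.alpha)
            sel_table = _selection_table(counts, neutral, consensus, config.alpha)
        except ValueError as exc:
            raise DataError(f"stage '{stage}' failed: {exc}") from exc

        counts.write(outdir / f"counts_{site_type}.tsv")
        _write(rates, outdir / f"rates_{site_type}.tsv", meta)
        _write(sel_table, outdir / f"selection_{site_type}.tsv", meta)
        results[f"rates_{site_type}"] = rates
        results[f"selection_{site_type}"] = sel_table
        log.info(
            "%s: %d records, %d ambiguous columns dropped, %d CpG-excluded",
            site_type,
            counts.n_records,
            int(counts.ambiguous.sum()),
            int(counts.excluded.sum()),
        )

        # drift load: pooled negative-direction S drives the per-locus s
        pooled_neg = sel_table[
            (sel_table["offset"] == "pooled") & (sel_table["direction"] == CN_TO_NC)
        ].iloc[0]
        s_locus = abs(per_locus_s(pooled_neg["S_hat"], config.Ne))
        mean_nc, cn_fraction = _nc_stats(ref_codes, offsets, site_type, consensus)
        n_ss = config.load_n_ss if config.load_n_ss is not None else counts.n_records
        load = drift_load(n_ss, mean_nc, s_locus, cn_fraction)
        load_df = pd.DataFrame([dataclasses.asdict(load)])
        _write(load_df, outdir / f"load_{site_type}.tsv", meta)
        results[f"load_{site_type}"] = load

        if config.run_conservation and config.mode == "synthetic":
            stage = f"{site_type} conservation"
            try:
                panel_params = _sim_params(
                    config, site_type, n_sites=min(config.panel_sites, config.n_sites)
                )
                panel = simulate_panel(panel_params)
                cons = _conservation_table(
                    panel,
                    consensus,
                    site_type,
                    B=config.bootstrap_B,
                    seed=int(config.seed or 0),
                )
            except ValueError as exc:
                raise DataError(f"stage '{stage}' failed: {exc}") from exc
            _write(cons, outdir / f"conservation_{site_type}.tsv", meta)
            results[f"conservation_{site_type}"] = cons

        # stratified reruns of the counting + inference stages
        if config.stratifiers and config.mode == "synthetic":
            strata_frames = []
            fractions = None
            for strat in config.stratifiers:
                if strat == "strength_class":
                    from .sites import ss_strength

                    recs = ens.to_records()
                    fractions = [ss_strength(r, consensus) for r in recs]
                    labels, _ = assign_strength_classes(fractions)
                else:
                    # synthetic ensembles carry a single class; one stratum
                    labels = ["all"] * counts.n_records
                for lab in sorted(set(labels)):
                    idx = np.flatnonzero(np.array(labels) == lab)
                    sub = TripletEnsemble(
                        site_type=ens.site_type,
                        offsets=ens.offsets,
                        ref=ens.ref[idx],
                        sister=ens.sister[idx],
                        outgroup=ens.outgroup[idx],
                        anc_true=ens.anc_true[idx],
                        truth_S=ens.truth_S[idx],
                        favored=ens.favored[idx],
                        consensus=consensus,
                        controls=ens.controls,
                        params=ens.params,
                    )
                    sub_counts = count_substitutions(
                        sub,
                        consensus,
                        exclude_cpg=config.exclude_cpg,
                        polarization=config.polarization,
                    )
                    sub_rates = offset_table(
                        sub_counts, neutral, consensus, alpha=config.alpha
                    )
                    sub_rates.insert(0, "stratifier", strat)
                    sub_rates.insert(1, "stratum", lab)
                    sub_rates.insert(2, "n_records", len(idx))
                    strata_frames.append(sub_rates)
            if strata_frames:
                strata = pd.concat(strata_frames, ignore_index=True)
                _write(strata, outdir / f"strata_{site_type}.tsv", meta)
                results[f"strata_{site_type}"] = strata

    manifest = {
        "config": config.to_dict(),
        "config_hash": meta["config_hash"],
        "seed": config.seed,
        "versions": {
            "splicesel": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
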