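"""End-to-end orchestration: simulate/load -> confound regression -> MODWT ->
correlation -> fixed-density graph -> efficiency -> group comparison ->
mediation, with every intermediate written to a run directory.

A run is fully determined by its configuration (hashed into the run
manifest): re-running with an identical config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .efficiency import efficiency_record, efficiency_table
from .graphs import correlation_matrix, threshold_to_density
from .inference import compare_cohort, results_table
from .mediation import PathModelSpec, fit_path_model, indirect_effect, residualize, trim_model
from .parcellation import ParcelTable
from .synthetic import Cohort, CohortConfig, SubjectTimeSeries, generate_cohort
from .wavelets import modwt, regress_confounds

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "subject_connectivity"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the subject id."""

    def __init__(self, stage: str, subject_id: str | None, cause: Exception):
        detail = f" (subject {subject_id})" if subject_id else ""
        super().__init__(f"stage {stage!r} failed{detail}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline parameters; defaults mirror the study protocol
    (TR 0.72 s, 6 MODWT levels, band of interest at level 4, 5% density)."""

    tr_seconds: float = 0.72
    wavelet_levels: int = 6
    level_of_interest: int = 4
    drop_boundary: bool = False
    density: float = 0.05
    threshold_mode: Literal["signed", "absolute"] = "signed"
    efficiency_mode: Literal["induced", "restricted"] = "induced"
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    simulate: CohortConfig | None = None
    input_dir: str | None = None
    confounds_dir: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.level_of_interest <= self.wavelet_levels:
            raise ValueError("level_of_interest must be within 1..wavelet_levels")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either a simulation config or an input directory is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["n_per_group"] = list(self.simulate.n_per_group)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            if "n_per_group" in sim:
                sim["n_per_group"] = tuple(sim["n_per_group"])
            sim = CohortConfig(**sim)
        return cls(simulate=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def subject_connectivity(
    data: np.ndarray,
    config: PipelineConfig,
    region_ids=None,
    confounds: pd.DataFrame | None = None,
):
    """One subject's pipeline core: (confound regression) -> MODWT ->
    level-of-interest correlation -> fixed-density binary graph."""
    if confounds is not None:
        data = regress_confounds(data, confounds)
    dec = modwt(
        data, levels=config.wavelet_levels, filter_name="la8", tr_seconds=config.tr_seconds
    )
    coeffs = dec.coefficients(config.level_of_interest, drop_boundary=config.drop_boundary)
    corr = correlation_matrix(coeffs, region_ids=region_ids)
    adj = threshold_to_density(corr, config.density, mode=config.threshold_mode)
    return corr, adj


def _load_inputs(config: PipelineConfig):
    input_dir = Path(config.input_dir)
    parcels = ParcelTable.read_tsv(input_dir / "parcels.tsv")
    manifest = pd.read_csv(input_dir / "manifest.tsv", sep="\t")
    timeseries = {
        sid: SubjectTimeSeries.read_tsv(
            input_dir / "timeseries" / f"{sid}.tsv", tr_seconds=config.tr_seconds, subject_id=sid
        )
        for sid in manifest["subject_id"]
    }
    return parcels, manifest, timeseries


def _default_mediation_spec(networks, score_cols) -> PathModelSpec:
    """Initial hypothesis model: group -> every network efficiency and every
    score; every network efficiency -> every score."""
    variables = ["group", *(f"E_{n}" for n in networks), *score_cols]
    edges: list[tuple[str, str]] = []
    for n in networks:
        edges.append(("group", f"E_{n}"))
    for s in score_cols:
        edges.append(("group", s))
        for n in networks:
            edges.append((f"E_{n}", s))
    return PathModelSpec(tuple(variables), tuple(edges))


def run_mediation(
    eff_table: pd.DataFrame,
    manifest: pd.DataFrame,
    networks,
    config: PipelineConfig,
    trim: bool = True,
) -> dict:
    """Residualize, fit/trim the path model, bootstrap surviving indirect
    effects of group through each network efficiency. Returns a JSON-ready
    dict."""
    merged = eff_table.merge(manifest, on="subject_id", validate="one_to_one")
    score_cols = [c for c in manifest.columns if c.startswith("score_")]
    eff_cols = [f"E_{n}" for n in networks]
    table = pd.DataFrame({"group": (merged["group"] == "IC").astype(float)})
    for c in eff_cols + score_cols:
        table[c] = merged[c].to_numpy(dtype=float)
    covs = []
    if "sex" in merged.columns:
        table["sex"] = (merged["sex"] == "M").astype(float)
        covs.append("sex")
    if "age" in merged.columns:
        table["age"] = merged["age"].to_numpy(dtype=float)
        covs.append("age")
    for c in merged.columns:
        if c.startswith("cov_"):
            table[c] = merged[c].to_numpy(dtype=float)
            covs.append(c)
    if covs:
        table = residualize(table, eff_cols + score_cols, covs)

    spec = _default_mediation_spec(networks, score_cols)
    if len(table) <= len(spec.variables):
        return {
            "skipped": (
                f"path model needs more subjects than variables "
                f"(n={len(table)}, variables={len(spec.variables)})"
            )
        }
    if trim:
        spec, fit = trim_model(spec, table, alpha=config.fdr_alpha)
    else:
        fit = fit_path_model(spec, table)

    indirect = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    for n in networks:
        for s in score_cols:
            chain = ("group", f"E_{n}", s)
            if (chain[0], chain[1]) in spec.edges and (chain[1], chain[2]) in spec.edges:
                eff = indirect_effect(
                    spec, table, chain, n_boot=config.n_boot,
                    seed=int(rng.integers(2**31)),
                )
                indirect.append(
                    {
                        "path": list(eff.path),
                        "point_estimate": eff.point_estimate,
                        "ci_low": eff.ci_low,
                        "ci_high": eff.ci_high,
                        "n_boot": eff.n_boot,
                        "excludes_zero": bool(eff.ci_low > 0 or eff.ci_high < 0),
                    }
                )
    return {
        "model": spec.to_text(),
        "estimates": {
            f"{src}->{tgt}": {
                "unstandardized": e.unstandardized,
                "standardized": e.standardized,
                "se": e.se,
                "p": e.p,
            }
            for (src, tgt), e in fit.estimates.items()
        },
        "fit": {
            "chi_square": fit.chi_square,
            "df": fit.df,
            "p": fit.p_fit,
            "cfi": fit.cfi,
            "rmsea": fit.rmsea,
        },
        "r_squared": fit.r_squared,
        "indirect_effects": indirect,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage, writing all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        try:
            cohort = generate_cohort(config.simulate)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("simulate", None, exc) from exc
        cohort.write(out / "cohort")
        parcels, manifest = cohort.parcels, cohort.manifest()
        timeseries = cohort.timeseries
    else:
        parcels, manifest, timeseries = _load_inputs(config)

    records = []
    summaries = {}
    edges_dir = out / "graphs"
    edges_dir.mkdir(exist_ok=True)
    confounds_dir = Path(config.confounds_dir) if config.confounds_dir else None
    for sid in manifest["subject_id"]:
        try:
            confounds = None
            if confounds_dir is not None:
                cpath = confounds_dir / f"{sid}.tsv"
                if cpath.exists():
                    confounds = pd.read_csv(cpath, sep="\t")
            corr, adj = subject_connectivity(
                timeseries[sid].data, config,
                region_ids=parcels.region_ids, confounds=confounds,
            )
            records.append(efficiency_record(adj, parcels, sid, mode=config.efficiency_mode))
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("connectivity", sid, exc) from exc
        adj.edge_list().to_csv(edges_dir / f"{sid}_edges.tsv", sep="\t", index=False)
        summaries[sid] = {"edge_count": adj.edge_count, "threshold": adj.threshold}
    (out / "graphs" / "summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))

    eff = efficiency_table(records)
    eff.to_csv(out / "efficiency.tsv", sep="\t", index=False)

    try:
        comparisons = compare_cohort(eff, manifest)
    except Exception as exc:  # noqa: BLE001
        raise StageError("compare", None, exc) from exc
    results_table(comparisons).to_csv(out / "comparisons.tsv", sep="\t", index=False)

    try:
        mediation = run_mediation(eff, manifest, parcels.network_names, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("mediate", None, exc) from exc
    (out / "mediation.json").write_text(json.dumps(mediation, indent=2, sort_keys=True))

    (out / "run_manifest.json").write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "waveconn_version": __version__,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    return out
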