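"""End-to-end orchestration of the bimodal study.

The topology chain runs per subject and condition: Pearson connectome ->
pseudo-distance -> clique filtration -> H1 barcode -> volume-optimal cycles
-> subject scaffold; scaffolds are group-averaged per condition and
persistence centrality is read off the group scaffold, while degree
centrality is averaged across subjects.  The spectral chain runs IRASA per
subject and condition and averages band-power ratios across subjects.  The
stats stage assembles task-minus-rest differences and the cross-modal
comparison report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as tio
from .connectome import (
    CentralityVector,
    FunctionalConnectome,
    compute_fc,
    degree_centrality,
    to_pseudo_distance,
)
from .homology import (
    build_flag_filtration,
    compute_h1_barcode,
    extract_features,
    solver_counts,
)
from .scaffold import build_scaffold, group_average, persistence_centrality
from .spectral import (
    BandPowerRatios,
    CANONICAL_BANDS,
    band_power_ratio,
    irasa,
    log_spaced_bands,
)
from .stats import compare_modalities
from .synth import RegionalTimeSeriesSet, SyntheticStudyConfig, generate_bold_like, generate_meg_like

logger = logging.getLogger("topospectra")

__all__ = ["PipelineConfig", "run_study", "topology_chain", "spectral_chain"]


@dataclasses.dataclass
class PipelineConfig:
    """Serializable options for a full study run."""

    study: SyntheticStudyConfig = dataclasses.field(default_factory=SyntheticStudyConfig)
    band_scheme: str = "log32"  # "canonical" | "log32"
    bpr_component: str = "aperiodic"  # "aperiodic" | "periodic" | "total"
    bpr_denominator: str = "total_fullband"
    hset: tuple[float, ...] | None = None
    cluster_threshold_p: float = 0.05
    n_perm: int = 10000
    dc_include_negative: bool = False
    output_dir: str | None = None

    def band_edges(self) -> list[tuple[float, float]]:
        if self.band_scheme == "log32":
            return log_spaced_bands(2.0, 90.0, 32)
        if self.band_scheme == "canonical":
            return list(CANONICAL_BANDS.values())
        raise ValueError(f"unknown band scheme {self.band_scheme!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study"]["planted_rings"] = [
            dataclasses.asdict(r) for r in self.study.planted_rings
        ]
        return d

    def dump_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=False)


def topology_chain(
    ts: RegionalTimeSeriesSet | None = None,
    connectomes: Sequence[FunctionalConnectome] | None = None,
    condition: str | None = None,
    dc_include_negative: bool = False,
    cycle_method: str = "auto",
) -> dict:
    """FC -> filtration -> barcode -> optimal cycles -> scaffold -> PC/DC.

    Accepts either regional time series (one subject per leading axis) or
    precomputed connectomes; the two entry points are equivalent whenever the
    connectomes equal the Pearson matrices of the series.
    """
    if (ts is None) == (connectomes is None):
        raise ValueError("provide exactly one of time series or connectomes")
    if ts is not None:
        condition = condition or ts.condition
        connectomes = [
            compute_fc(ts.data[s], ts.region_labels) for s in range(ts.n_subjects)
        ]
    labels = connectomes[0].region_labels
    n = connectomes[0].n_regions
    scaffolds = []
    dcs = []
    n_intervals = 0
    n_infinite = 0
    fallbacks_before = solver_counts["lp_to_ilp_fallbacks"]
    for G in connectomes:
        D = to_pseudo_distance(G)
        F = build_flag_filtration(D)
        barcode = compute_h1_barcode(F)
        n_intervals += len(barcode.intervals)
        n_infinite += len(barcode.infinite_intervals)
        features = extract_features(F, barcode, method=cycle_method)
        scaffolds.append(
            build_scaffold(features, n, region_labels=labels, condition=condition)
        )
        dcs.append(degree_centrality(G, include_negative=dc_include_negative))
    group = group_average(scaffolds)
    pc = persistence_centrality(group)
    dc_mean = CentralityVector(
        values=np.mean([d.values for d in dcs], axis=0),
        kind="DC",
        region_labels=labels,
        condition=condition,
    )
    n_fallbacks = solver_counts["lp_to_ilp_fallbacks"] - fallbacks_before
    logger.info(
        "topology[%s]: %d finite intervals, %d infinite (excluded from "
        "scaffolds), %d LP->ILP fallbacks",
        condition, n_intervals, n_infinite, n_fallbacks,
    )
    return {
        "condition": condition,
        "scaffold": group,
        "pc": pc,
        "dc": dc_mean,
        "n_intervals": n_intervals,
        "n_infinite": n_infinite,
        "n_lp_to_ilp_fallbacks": n_fallbacks,
    }


def spectral_chain(
    ts: RegionalTimeSeriesSet,
    band_edges: Sequence[tuple[float, float]],
    component: str = "aperiodic",
    denominator: str = "total_fullband",
    hset: Sequence[float] | None = None,
) -> BandPowerRatios:
    """IRASA per subject, subject-averaged band-power ratios.

    Rows of all subjects are stacked into a single decomposition (IRASA and
    the band integrals act on each row independently), then the per-subject
    ratios are averaged.
    """
    kw = {} if hset is None else {"hset": hset}
    n_s, n_r, n_t = ts.data.shape
    stacked = ts.data.reshape(n_s * n_r, n_t)
    stacked_labels = [f"s{s}:{r}" for s in range(n_s) for r in ts.region_labels]
    decomp = irasa(stacked, ts.fs, region_labels=stacked_labels, **kw)
    all_bpr = band_power_ratio(
        decomp, band_edges, component=component, denominator=denominator
    ).bpr
    return BandPowerRatios(
        band_edges=tuple(band_edges),
        bpr=all_bpr.reshape(n_s, n_r, -1).mean(axis=0),
        region_labels=ts.region_labels,
        component=component,
    )


def run_study(config: PipelineConfig, seed: int | None = None) -> dict:
    """Generate the synthetic study and run both chains plus the stats stage.

    ``seed`` overrides the study config's master seed.  When
    ``config.output_dir`` is set, all intermediates (connectomes, scaffolds,
    centralities, band-power tables) and the JSON report are written there.
    """
    study = config.study
    if seed is not None:
        study = dataclasses.replace(study, seed=int(seed))
    band_edges = config.band_edges()

    pc, dc, bpr = {}, {}, {}
    counts = {}
    for condition in study.conditions:
        bold = generate_bold_like(study, condition)
        topo = topology_chain(
            ts=bold, dc_include_negative=config.dc_include_negative
        )
        pc[condition] = topo["pc"]
        dc[condition] = topo["dc"]
        counts[condition] = {
            "n_intervals": topo["n_intervals"],
            "n_infinite": topo["n_infinite"],
        }
        meg = generate_meg_like(study, condition)
        bpr[condition] = spectral_chain(
            meg,
            band_edges,
            component=config.bpr_component,
            denominator=config.bpr_denominator,
            hset=config.hset,
        )

    tasks = list(study.task_conditions)
    report = compare_modalities(
        pc_rest=pc["rest"],
        pc_tasks={t: pc[t] for t in tasks},
        dc_rest=dc["rest"],
        dc_tasks={t: dc[t] for t in tasks},
        bpr_rest=bpr["rest"],
        bpr_tasks={t: bpr[t] for t in tasks},
        threshold_p=config.cluster_threshold_p,
        n_perm=config.n_perm,
        seed=study.seed,
    )
    report["interval_counts"] = counts
    report["config"] = config.to_dict()
    report["pc"] = pc
    report["dc"] = dc
    report["bpr"] = bpr

    if config.output_dir is not None:
        _write_outputs(Path(config.output_dir), config, report)
    return report


def _serializable_report(report: dict) -> dict:
    out = {
        "tasks": report["tasks"],
        "band_edges": report["band_edges"],
        "theta_alpha_bands": report["theta_alpha_bands"],
        "cos_pc": np.asarray(report["cos_pc"]).tolist(),
        "cos_dc": np.asarray(report["cos_dc"]).tolist(),
        "abs_cos_pc_mean": np.asarray(report["abs_cos_pc_mean"]).tolist(),
        "abs_cos_dc_mean": np.asarray(report["abs_cos_dc_mean"]).tolist(),
        "kendall_rest_pc_vs_dpc": {
            k: list(v) for k, v in report["kendall_rest_pc_vs_dpc"].items()
        },
        "interval_counts": report["interval_counts"],
        "config": report["config"],
    }
    ct = report["cluster_test"]
    if ct is not None:
        out["cluster_test"] = {
            "exact": ct.exact,
            "n_permutations": ct.n_permutations,
            "t_threshold": ct.t_threshold,
            "clusters": [
                {
                    "band_start": c.band_start,
                    "band_stop": c.band_stop,
                    "mass": c.mass,
                    "p_value": c.p_value,
                }
                for c in ct.clusters
            ],
        }
    else:
        out["cluster_test"] = None
    return out


def _write_outputs(outdir: Path, config: PipelineConfig, report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.dump_yaml())
    labels = None
    for condition, vec in report["pc"].items():
        labels = list(vec.region_labels)
        tio.write_centrality(
            outdir / f"centrality_{condition}.tsv",
            [report["pc"][condition], report["dc"][condition]],
            ["PC", "DC"],
        )
        b = report["bpr"][condition]
        import pandas as pd

        pd.DataFrame(
            b.bpr,
            index=labels,
            columns=[f"{lo:.3f}-{hi:.3f}Hz" for lo, hi in b.band_edges],
        ).to_csv(outdir / f"bpr_{condition}.tsv", sep="\t", float_format="%.10g")
    with open(outdir / "report.json", "w") as fh:
        json.dump(_serializable_report(report), fh, indent=2)
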