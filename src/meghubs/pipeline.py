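"""Subject- and group-level orchestration.

One :class:`PipelineConfig` carries every stage parameter; a subject run
executes the fixed stage order

    preprocess → invert → stats → connect → network

and returns (optionally writing as TSV) the differential-power map, the
task-related adjacency, voxel centralities, parcel metrics and the
laterality index. Stage seeds are derived from the master seed by
stable hashing of the stage name, so inserting a stage never perturbs
the randomness of later stages, and a repeated run is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import connectivity, inversion, network, preprocessing, stats
from .containers import WindowPair
from .io import SubjectData
from .synthetic import (
    ParcelAtlas,
    SimulationScenario,
    build_head_and_sensors,
    build_source_grid,
    build_synthetic_atlas,
    compute_leadfield,
    draw_tangential_orientations,
    project_and_add_noise,
    simulate_trial_sources,
)

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "stage_seed",
    "simulate_subject",
    "run_subject",
    "run_group",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹ from the master seed."""
    h = hashlib.blake2s(f"{stage}|{master_seed}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "little") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with their study defaults."""

    epoch_window: Tuple[float, float] = (-0.9, 1.8)
    baseline_correct_window: Tuple[float, float] = (-0.9, 0.0)
    line_freqs: Tuple[float, ...] = (60.0, 120.0, 180.0)
    bandpass_band: Tuple[float, float] = (0.1, 100.0)
    baseline_window: Tuple[float, float] = (-0.4, 0.0)
    active_window: Tuple[float, float] = (0.6, 1.0)
    jump_z_threshold: float = 20.0
    grid_spacing: float = 0.01
    lcmv_lambda: float = 0.001
    erd_band: Tuple[float, float] = (13.0, 23.0)
    n_rand: int = 5000
    fdr_q: float = 0.05
    plv_band: Tuple[float, float] = (3.0, 30.0)
    plv_min_cycles: float = 2.0
    graph_threshold: float = 0.7
    edge_sign: str = "positive"
    li_cutoff: float = 0.25
    master_seed: int = 0

    def validate(self) -> None:
        WindowPair(baseline=self.baseline_window, active=self.active_window)
        if not (0 < self.graph_threshold <= 1):
            raise ValueError("graph_threshold must be in (0, 1]")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.n_rand < 1:
            raise ValueError("n_rand must be positive")
        if self.lcmv_lambda < 0:
            raise ValueError("lcmv_lambda must be non-negative")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.blake2s(
            json.dumps(asdict(self), sort_keys=True).encode(), digest_size=8
        ).hexdigest()


@dataclass
class SubjectResult:
    erd: inversion.ERDMap
    adjacency: connectivity.AdjacencyMatrix
    centrality: network.CentralityMap
    parcels: pd.DataFrame
    laterality: network.LateralityResult
    n_trials_kept: int
    provenance: Dict = field(default_factory=dict)


def simulate_subject(
    scenario: SimulationScenario,
    n_chan: int = 275,
    head_radius: float = 0.09,
    sensor_shell_radius: float = 0.12,
    grid_spacing: float = 0.01,
    n_parcels_per_hemisphere: int = 8,
) -> SubjectData:
    """Build one complete synthetic subject from a scenario description."""
    head, sensors = build_head_and_sensors(
        n_chan=n_chan, head_radius=head_radius,
        sensor_shell_radius=sensor_shell_radius, seed=scenario.seed,
    )
    grid = build_source_grid(head, grid_spacing)
    leadfield = compute_leadfield(grid, sensors, head)
    ori = draw_tangential_orientations(grid, head, seed=scenario.seed + 1)
    sources = simulate_trial_sources(scenario, grid)
    epochs = project_and_add_noise(
        sources, leadfield, ori, scenario.noise_sd, seed=scenario.seed + 2,
        sfreq=scenario.sfreq, times=scenario.times(),
        chan_pos=sensors.positions, chan_ori=sensors.orientations,
    )
    atlas = build_synthetic_atlas(grid, n_parcels_per_hemisphere, seed=scenario.seed + 3)
    truth = {
        "erd_voxels": [int(v) for v in scenario.erd_voxels],
        "erd_depth": scenario.erd_depth,
        "coupled_pairs": [[int(i), int(j), float(c)] for i, j, c in scenario.coupled_pairs],
        "seed": scenario.seed,
    }
    return SubjectData(
        epochs=epochs, head=head, grid=grid, leadfield=leadfield,
        source_orientations=ori, atlas=atlas, truth=truth,
    )


def run_subject(
    config: PipelineConfig,
    data: SubjectData,
    atlas: Optional[ParcelAtlas] = None,
    out_dir: Optional[str] = None,
) -> SubjectResult:
    """Execute the full subject-level pipeline on one dataset.

    Deterministic: re-running with the same config and data is
    bit-identical (the permutation seed is derived from the master
    seed). When ``out_dir`` is given, the differential-power map, parcel
    metrics, laterality and a JSON manifest are written as text.
    """
    config.validate()
    atlas = atlas if atlas is not None else data.atlas
    if atlas is None:
        raise ValueError("no parcel atlas available for this subject")

    # --- preprocess -------------------------------------------------------
    epochs = preprocessing.baseline_correct(data.epochs, config.baseline_correct_window)
    epochs = preprocessing.attenuate_line_noise(epochs, config.line_freqs)
    epochs = preprocessing.bandpass(epochs, config.bandpass_band)
    if epochs.n_trials >= 8:
        epochs = preprocessing.reject_jump_trials(epochs, config.jump_z_threshold)
    windows = WindowPair(baseline=config.baseline_window, active=config.active_window)
    base, act = preprocessing.extract_windows(epochs, windows)

    # --- invert -----------------------------------------------------------
    cov = inversion.common_covariance(base, act)
    weights = inversion.lcmv_weights(
        data.leadfield, cov, lam=config.lcmv_lambda, grid=data.grid, head=data.head
    )
    src_base = inversion.project_sources(weights, base)
    src_act = inversion.project_sources(weights, act)

    # --- differential power + permutation stats ---------------------------
    erd = inversion.differential_band_power(src_base, src_act, band=config.erd_band)
    perm = stats.permutation_erd_test(
        erd.active_power, erd.baseline_power,
        n_rand=config.n_rand, seed=stage_seed(config.master_seed, "stats"),
    )
    erd.t_stat = perm.observed_t
    erd.p_value = perm.p_values
    erd.significant_mask = stats.fdr_bh(perm.p_values, q=config.fdr_q)

    # --- connectivity ------------------------------------------------------
    ph_base = connectivity.trial_spectral_phases(src_base, config.plv_band, config.plv_min_cycles)
    ph_act = connectivity.trial_spectral_phases(src_act, config.plv_band, config.plv_min_cycles)
    adj = connectivity.plv_adjacency(ph_act, ph_base)

    # --- network -----------------------------------------------------------
    graph = network.binarize_by_max_fraction(adj, config.graph_threshold, config.edge_sign)
    cmap = network.centrality_map(graph)
    parcels = network.parcellate_and_scale(cmap, atlas)
    lat = network.laterality_index(parcels, metric="evc", cutoff=config.li_cutoff)

    result = SubjectResult(
        erd=erd, adjacency=adj, centrality=cmap, parcels=parcels,
        laterality=lat, n_trials_kept=int(epochs.trial_keep_mask.sum()),
        provenance={
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "stats_seed": stage_seed(config.master_seed, "stats"),
        },
    )
    if out_dir is not None:
        _write_subject_outputs(result, data, out_dir)
    return result


def _fmt(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_subject_outputs(result: SubjectResult, data: SubjectData, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    erd = result.erd
    erd_df = pd.DataFrame(
        {
            "voxel_index": np.arange(len(erd.rel_power_change)),
            "x": data.grid.points[:, 0],
            "y": data.grid.points[:, 1],
            "z": data.grid.points[:, 2],
            "rel_power_change": erd.rel_power_change,
            "t": erd.t_stat,
            "p": erd.p_value,
            "significant": erd.significant_mask.astype(int),
        }
    )
    _fmt(erd_df, os.path.join(out_dir, "erd_map.tsv"))
    cent_df = pd.DataFrame(
        {
            "voxel_index": np.arange(len(result.centrality.degree)),
            "degree": result.centrality.degree,
            "evc": result.centrality.evc,
            "betweenness": result.centrality.betweenness,
        }
    )
    _fmt(cent_df, os.path.join(out_dir, "centrality.tsv"))
    _fmt(result.parcels, os.path.join(out_dir, "parcel_metrics.tsv"))
    lat_df = pd.DataFrame(
        [
            {
                "li": result.laterality.li,
                "category": result.laterality.category,
                "L": result.laterality.L,
                "R": result.laterality.R,
            }
        ]
    )
    _fmt(lat_df, os.path.join(out_dir, "laterality.tsv"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(
            {
                "provenance": result.provenance,
                "n_trials_kept": result.n_trials_kept,
                "laterality": result.laterality.category,
            },
            fh, indent=2, sort_keys=True,
        )


def run_group(
    config: PipelineConfig,
    subject_results: Sequence[SubjectResult],
    group_labels: Sequence[str],
) -> Dict:
    """Group-level aggregation and contrast.

    Per label: mean parcel metrics scaled to [0, 1]; between the two
    labels: an independent-samples t contrast on parcel EVC with BH-FDR;
    plus a laterality summary table with per-label category counts.
    """
    if len(subject_results) != len(group_labels):
        raise ValueError("one label per subject required")
    labels = sorted(set(group_labels))
    by_label: Dict[str, List[SubjectResult]] = {lab: [] for lab in labels}
    for res, lab in zip(subject_results, group_labels):
        by_label[lab].append(res)
    for lab in labels:
        if len(by_label[lab]) < 2:
            raise ValueError(f"group '{lab}' has fewer than 2 subjects")
    ref_parcels = subject_results[0].parcels["parcel"].to_numpy()
    for res in subject_results[1:]:
        if not np.array_equal(res.parcels["parcel"].to_numpy(), ref_parcels):
            raise ValueError("subjects use mismatched atlases")

    group_means: Dict[str, pd.DataFrame] = {}
    for lab in labels:
        dfs = [r.parcels for r in by_label[lab]]
        mean = dfs[0][["parcel", "name", "hemisphere", "lobe"]].copy()
        for col in ("degree", "evc", "betweenness"):
            stack = np.column_stack([df[col].to_numpy() for df in dfs])
            mcol = stack.mean(axis=1)
            mx = np.nanmax(mcol)
            mean[col] = mcol / mx if mx > 0 else mcol
        group_means[lab] = mean

    contrast = None
    if len(labels) == 2:
        contrast = network.group_contrast(
            [r.parcels for r in by_label[labels[0]]],
            [r.parcels for r in by_label[labels[1]]],
            metric="evc", q=config.fdr_q,
        )

    li_rows = []
    for res, lab in zip(subject_results, group_labels):
        li_rows.append({"group": lab, "li": res.laterality.li, "category": res.laterality.category})
    li_table = pd.DataFrame(li_rows)
    li_counts = (
        li_table.groupby(["group", "category"]).size().unstack(fill_value=0)
    )
    return {
        "group_means": group_means,
        "contrast": contrast,
        "li_table": li_table,
        "li_counts": li_counts,
    }
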