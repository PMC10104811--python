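"""Config-driven orchestration of the full disparity analysis.

Stages, in order: ingest (files or simulation) -> group filter -> outline
resampling -> EFA -> normalisation -> coefficient matrix -> PCA
morphospace -> per-PC ranges -> bootstrap/rarefied disparity -> pairwise
tests -> report bundle.  Every stage logs record counts; outputs are
byte-stable for identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import efa, morphospace, outline_io, synthetic
from .disparity import (
    TEST_METHOD_LABEL,
    DisparityResult,
    bootstrap_disparity,
    pairwise_compare,
    subset_seed,
    tests_table,
)

log = logging.getLogger("morphodisp")

__all__ = ["PipelineConfig", "run_pipeline", "make_figures"]

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """All knobs of the analysis; round-trips losslessly through YAML.

    Either ``tps_path`` (+ ``labels_path``) point at input files, or
    ``simulate`` requests the built-in synthetic design ("default" or a
    mapping accepted by :func:`morphodisp.synthetic.SamplingDesign`).
    ``rarefaction`` is "smaller-group" (each subset bootstrapped at the
    size of its group's smallest time-slice subset), a fixed integer, or
    "none".  ``comparison_pairs`` is "all" (every within-group pair of
    time slices) or an explicit list of [group/slice, group/slice] pairs.
    """

    tps_path: str | None = None
    labels_path: str | None = None
    chaincode_path: str | None = None
    simulate: str | None = None
    exclude_groups: list[str] = field(default_factory=list)
    n_harmonics: int = 20
    resample_k: int = 200
    allow_reflection: bool = False
    n_boot: int = 10_000
    rarefaction: str | int = "smaller-group"
    seed: int = 20230913
    comparison_pairs: str | list = "all"
    alpha: float = 0.05
    refit_after_exclusion: bool = True
    out_dir: str = "morphodisp_out"

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _ingest(config: PipelineConfig) -> outline_io.Dataset:
    if config.simulate is not None:
        if config.simulate != "default":
            raise ValueError("simulate must be 'default' or omitted")
        design = synthetic.default_paper_design(root_seed=config.seed)
        dataset, _truth = synthetic.generate_dataset(design, k_points=config.resample_k)
        return dataset
    if config.tps_path:
        return outline_io.read_tps(
            config.tps_path, labels=config.labels_path, require_labels=True
        )
    if config.chaincode_path:
        return outline_io.read_chaincode(config.chaincode_path)
    raise ValueError("config must give tps_path, chaincode_path or simulate")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory artefacts (dataset, model, tables)
    and writes: dataset manifest, coefficient CSV, scores CSV + model
    JSON, per-PC range CSV, disparity CSV, pairwise-test CSV and a run
    manifest with config hash, seed and per-stage record counts.  Subsets
    with fewer than 2 specimens are skipped from disparity with a logged
    warning; an empty dataset after group exclusion is an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    dataset = _ingest(config)
    counts["ingested"] = len(dataset)
    log.info("ingested %d outlines", len(dataset))

    dataset = dataset.filter_groups(config.exclude_groups).require_labels()
    counts["after_exclusion"] = len(dataset)
    if config.exclude_groups:
        log.info(
            "excluded groups %s: %d -> %d specimens",
            config.exclude_groups,
            counts["ingested"],
            len(dataset),
        )
    if len(dataset) == 0:
        raise ValueError("dataset empty after group exclusion")
    _write_csv(dataset.metadata(), out / "dataset_manifest.csv")

    # EFA on arc-length-resampled outlines
    nefds = []
    for o in dataset:
        o = outline_io.resample_outline(o, config.resample_k)
        e = efa.compute_efd(o, n_harmonics=config.n_harmonics)
        nefds.append(efa.normalize_efd(e, allow_reflection=config.allow_reflection))
    coeffs = efa.coefficient_matrix(nefds)
    counts["coefficients"] = len(coeffs)
    outline_io.write_coeff_table(coeffs, out / "coefficients.csv")

    model = morphospace.fit_pca(coeffs)
    counts["scores"] = len(model.scores)
    _write_csv(model.scores, out / "scores.csv")
    model.to_json(out / "model.json")

    ranges = morphospace.pc_ranges(model)
    _write_csv(ranges, out / "pc_ranges.csv")

    # disparity per group x time slice
    sc = model.scores
    pc_cols = model.pc_columns
    results: list[DisparityResult] = []
    skipped: list[str] = []
    for group in sorted(sc["group"].unique()):
        gsc = sc[sc["group"] == group]
        sizes = gsc.groupby("time_slice").size()
        usable = sizes[sizes >= 2]
        for slice_, n in sizes.items():
            if n < 2:
                skipped.append(f"{group}/{slice_}")
                log.warning("subset %s/%s has n=%d < 2; skipped", group, slice_, n)
        if usable.empty:
            continue
        if config.rarefaction == "smaller-group":
            m_group = int(usable.min())
        elif config.rarefaction == "none":
            m_group = None
        else:
            m_group = int(config.rarefaction)
        for slice_ in sorted(usable.index):
            sub = gsc[gsc["time_slice"] == slice_][pc_cols].to_numpy()
            m = m_group if m_group is None else min(m_group, len(sub))
            results.append(
                bootstrap_disparity(
                    sub,
                    n_boot=config.n_boot,
                    rarefaction_size=m,
                    seed=subset_seed(config.seed, group, slice_),
                    group=group,
                    time_slice=slice_,
                )
            )
    disparity_df = pd.DataFrame([r.summary() for r in results])
    _write_csv(disparity_df, out / "disparity.csv")

    # pairwise tests on replicate vectors
    if config.comparison_pairs == "all":
        pairs = []
        for group in sorted({r.group for r in results}):
            labels = sorted(r.label for r in results if r.group == group)
            pairs += [
                (labels[i], labels[j])
                for i in range(len(labels))
                for j in range(i + 1, len(labels))
            ]
    else:
        pairs = [tuple(p) for p in config.comparison_pairs]
    tests_df = pd.DataFrame(
        columns=[
            "subset_a",
            "subset_b",
            "t",
            "df",
            "p_raw",
            "p_bonferroni",
            "m_comparisons",
            "method",
        ]
    )
    test_results = []
    if pairs and len(results) >= 2:
        test_results = pairwise_compare(results, pairs=pairs)
        tests_df = tests_table(test_results)
    _write_csv(tests_df, out / "tests.csv")

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": _version(),
        "stage_counts": counts,
        "skipped_subsets": skipped,
        "n_retained_pcs": model.n_retained,
        "tests_method": TEST_METHOD_LABEL,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "dataset": dataset,
        "coefficients": coeffs,
        "model": model,
        "ranges": ranges,
        "disparity_results": results,
        "disparity": disparity_df,
        "tests": tests_df,
        "test_results": test_results,
        "manifest": manifest,
        "out_dir": str(out),
    }


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# Figures


def make_figures(bundle: dict, out_dir: str | os.PathLike | None = None) -> list[str]:
    """Render the report figures from a pipeline bundle.

    PC1-PC2 and PC1-PC3 scatterplots coloured by group and faceted by
    time slice, box summaries of the bootstrap sum-of-variances
    distributions, and per-PC range bars.  File names are deterministic.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir if out_dir is not None else bundle["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    model = bundle["model"]
    sc = model.scores
    slices = [s for s in outline_io.TIME_SLICES if s in set(sc["time_slice"])]
    groups = sorted(sc["group"].unique())
    cmap = plt.get_cmap("tab10")
    colors = {g: cmap(i % 10) for i, g in enumerate(groups)}

    pairs = [("PC1", "PC2"), ("PC1", "PC3")]
    for px, py in pairs:
        if py not in sc.columns:
            continue
        fig, axes = plt.subplots(
            1, len(slices), figsize=(4 * len(slices), 4), sharex=True, sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, slice_ in zip(axes, slices):
            sub = sc[sc["time_slice"] == slice_]
            for g in groups:
                gsub = sub[sub["group"] == g]
                if len(gsub):
                    ax.scatter(gsub[px], gsub[py], s=8, color=colors[g], label=g)
            ax.set_title(slice_)
            ax.set_xlabel(px)
        axes[0].set_ylabel(py)
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        name = f"scatter_{px}_{py}.png"
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        written.append(name)

    results = bundle["disparity_results"]
    if results:
        fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(results)), 4))
        ax.boxplot(
            [r.replicates for r in results],
            tick_labels=[r.label for r in results],
            showfliers=False,
        )
        ax.set_ylabel("sum of variances (bootstrap, rarefied)")
        ax.tick_params(axis="x", rotation=75)
        fig.tight_layout()
        fig.savefig(out / "disparity_boxes.png", dpi=120)
        plt.close(fig)
        written.append("disparity_boxes.png")

    ranges = bundle["ranges"]
    top = [pc for pc in ("PC1", "PC2") if pc in set(ranges["pc"])]
    if top:
        fig, axes = plt.subplots(1, len(top), figsize=(6 * len(top), 4), sharey=False)
        axes = np.atleast_1d(axes)
        for ax, pc in zip(axes, top):
            sub = ranges[(ranges["pc"] == pc) & (ranges["n"] > 0)]
            labels = sub["group"] + "/" + sub["time_slice"]
            ax.bar(labels, sub["range"])
            ax.set_title(f"{pc} score range (untreated data)")
            ax.tick_params(axis="x", rotation=75, labelsize=7)
        fig.tight_layout()
        fig.savefig(out / "pc_ranges.png", dpi=120)
        plt.close(fig)
        written.append("pc_ranges.png")
    return written
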