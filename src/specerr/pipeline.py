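"""Full analysis pipeline: descriptives → T²/Q screen → Σ/R → decomposition → K.

``run_pipeline`` orchestrates the whole chain per sample, writing the report
bundle (tables as CSV, figures as PNG, a JSON manifest echoing the
configuration and the seed) to an output directory. Outliers are screened and
reported by default but only removed when the configuration says so — removal
then precedes the error-covariance stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ReplicateGrouping, SpectraDataset, read_spectra
from .descriptives import summary_table
from .kindex import imbedded_correlation, k_index
from .model import MeasurementErrorModel
from .plots import render_diagonals, render_heatmap
from .screening import SpectralPCA
from .simulate import DesignSpec, NoiseModel, PROFILES, simulate_dataset
from .error_structure import error_covariance, error_matrix

logger = logging.getLogger("specerr")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``simulate`` must be set; a seed is
    mandatory when simulating.
    """

    input_path: str | None = None
    simulate: dict | None = None       # DesignSpec/NoiseModel keyword groups
    grouping: str = "all"
    n_components: int = 5
    alpha: float = 0.05
    remove_outliers: str = "none"      # none | both | either
    out_dir: str = "specerr_report"
    seed: int | None = None
    table_format: str = "csv"          # csv | json

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.simulate is not None and self.seed is None:
            raise ValueError("a seed is required when simulating")
        if self.remove_outliers not in ("none", "both", "either"):
            raise ValueError("remove_outliers must be none, both or either")


def _load(config: RunConfig) -> SpectraDataset:
    if config.input_path is not None:
        return read_spectra(config.input_path)
    spec = dict(config.simulate or {})
    profile = spec.pop("instrument", "avaspec_like")
    if isinstance(profile, str):
        profile = PROFILES[profile]
    noise_kwargs = spec.pop("noise", {})
    design = DesignSpec(instrument=profile, **spec)
    noise = NoiseModel(**noise_kwargs)
    return simulate_dataset(design, noise, seed=config.seed)


def _write_table(df: pd.DataFrame, path: Path, fmt: str) -> Path:
    if fmt == "json":
        path = path.with_suffix(".json")
        df.to_json(path, orient="split", double_precision=12)
    else:
        df.to_csv(path)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: list[Path] = []
    stage = "load"
    try:
        dataset = _load(config)
        logger.info("loaded %d replicates × %d channels", dataset.n, dataset.p)

        stage = "descriptives"
        desc = summary_table(dataset)
        artifacts.append(_write_table(desc, out / "descriptives.csv",
                                      config.table_format))
        logger.info("descriptives: %d samples", desc.shape[1])

        stage = "outlier_screen"
        outlier_rows = []
        keep_mask = np.ones(dataset.n, dtype=bool)
        for sample in dataset.meta["sample_id"].unique():
            idx = np.flatnonzero((dataset.meta["sample_id"] == sample).to_numpy())
            sub = dataset.take(idx)
            k = min(config.n_components, sub.n - 1, sub.p)
            res = SpectralPCA(sub, n_components=k).fit()
            screen = res.screen(alpha=config.alpha)
            rule = config.remove_outliers if config.remove_outliers != "none" else "both"
            from .screening import flag_outliers
            flags = flag_outliers(screen, rule)
            for local_i in range(sub.n):
                outlier_rows.append({
                    "sample_id": sample,
                    "session_id": sub.meta.iloc[local_i]["session_id"],
                    "replicate_index": sub.meta.iloc[local_i]["replicate_index"],
                    "t2": screen.t2[local_i],
                    "q": screen.q[local_i],
                    "t2_limit": screen.t2_limit,
                    "q_limit": screen.q_limit,
                    "flagged": bool(flags[local_i]),
                })
            if config.remove_outliers != "none":
                keep_mask[idx[flags]] = False
        outlier_df = pd.DataFrame(outlier_rows)
        artifacts.append(_write_table(outlier_df, out / "outliers.csv",
                                      config.table_format))
        n_flagged = int(outlier_df["flagged"].sum())
        logger.info("outlier screen: %d replicate(s) flagged", n_flagged)
        if config.remove_outliers != "none" and not keep_mask.all():
            dataset = dataset.take(np.flatnonzero(keep_mask))
            logger.info("removed %d outlier(s); %d replicates remain",
                        int((~keep_mask).sum()), dataset.n)

        stage = "error_structure"
        grouping = ReplicateGrouping(config.grouping)
        report = dataset.validate(grouping)
        if not report.ok:
            raise ValueError(str(report))
        per_sample = {}
        vc_tables, k_rows = [], []
        for sample in dataset.meta["sample_id"].unique():
            sub = dataset.subset(sample_id=sample)
            fit = MeasurementErrorModel(
                sub, grouping=config.grouping, n_components=config.n_components
            ).fit()
            per_sample[sample] = fit
            tag = str(sample).replace("/", "_")
            sigma_path = out / f"sigma_{tag}.csv"
            artifacts.append(_write_table(fit.sigma.to_frame(), sigma_path,
                                          config.table_format))
            corr = fit.correlation
            corr_df = pd.DataFrame(corr.R, index=corr.wavelengths,
                                   columns=corr.wavelengths)
            artifacts.append(_write_table(corr_df, out / f"correlation_{tag}.csv",
                                          config.table_format))
            artifacts.append(render_heatmap(fit.sigma.Sigma, sub.axis,
                                            "covariance",
                                            out / f"sigma_heatmap_{tag}.png"))
            artifacts.append(render_heatmap(
                _expand_correlation(corr, sub.p), sub.axis, "correlation",
                out / f"correlation_heatmap_{tag}.png"))
            for mode_name, label in (("per_background_mode", "background"),
                                     ("per_session", "session")):
                diags = fit.diagonal_by(mode_name)
                diags.columns = [c.split("/", 1)[-1] for c in diags.columns]
                artifacts.append(render_diagonals(
                    {c: diags[c].to_numpy() for c in diags.columns}, sub.axis,
                    out / f"diagonals_{label}_{tag}.png"))
            vc = fit.variance_comparison.table.copy()
            vc.columns = pd.MultiIndex.from_product([[sample], vc.columns])
            vc_tables.append(vc)
            k_rows.append({
                "sample_id": sample,
                "grouping": config.grouping,
                "n": fit.error_mat.n,
                "p": fit.error_mat.p,
                "imbedded_correlation": fit.imbedded_correlation,
                "K": fit.k,
            })
            # per-session K values (Table-4 layout)
            for sess in sub.meta["session_id"].unique():
                sess_sub = sub.subset(session_id=sess)
                E = error_matrix(sess_sub, "all")
                k_rows.append({
                    "sample_id": sample,
                    "grouping": f"session {sess}",
                    "n": E.n,
                    "p": E.p,
                    "imbedded_correlation": imbedded_correlation(E.n, E.p),
                    "K": k_index(E).K,
                })
            logger.info("sample %s: K=%.4f gap=%.3f", sample, fit.k,
                        fit.uncorrelated_error_gap)

        stage = "variance_comparison"
        artifacts.append(_write_table(pd.concat(vc_tables, axis=1),
                                      out / "variance_comparison.csv",
                                      config.table_format))
        stage = "k_index"
        artifacts.append(_write_table(pd.DataFrame(k_rows).set_index("sample_id"),
                                      out / "kindex.csv", config.table_format))

        stage = "manifest"
        manifest = {
            "specerr_version": __version__,
            "config": {k: v for k, v in vars(config).items()},
            "seed": config.seed,
            "n_replicates": int(dataset.n),
            "n_channels": int(dataset.p),
            "outliers_flagged": n_flagged,
            "elapsed_s": round(time.time() - t0, 3),
            "artifacts": {p.name: _sha256(Path(p)) for p in artifacts},
            "complete": True,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
        return manifest
    except Exception as exc:
        partial = {
            "complete": False,
            "failed_stage": stage,
            "error": str(exc),
            "artifacts": {Path(p).name: _sha256(Path(p)) for p in artifacts},
        }
        (out / "manifest.json").write_text(json.dumps(partial, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _expand_correlation(corr, p: int) -> np.ndarray:
    """Embed a retained-channel correlation matrix back into p×p (zeros at
    excluded channels) for plotting."""
    R = np.zeros((p, p))
    R[np.ix_(corr.retained, corr.retained)] = corr.R
    return R
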