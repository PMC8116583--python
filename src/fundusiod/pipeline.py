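"""End-to-end orchestration: synthesize or load a dataset, extract the
feature pool, select features, fit the indicator models and evaluate them.

Every run directory is self-describing: it contains the serialized config,
package version, per-stage timing, per-case flags, the feature table, the
selection path, the fitted model JSONs and the evaluation reports.  With a
fixed config and seed the CSV/JSON outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, case_io
from .case_io import FeatureTable
from .cohort_stats import evaluate_iod
from .feature_pool import DEFAULT_BIN_WIDTH, extract_pool
from .iod_model import (IODModel, SelectionPath, fit_iod, lasso_order,
                        select_feature_count, split_cohort)
from .roi_geometry import build_roi_masks, littmann_scale
from .synth_cohort import (CohortParams, camera_constant_for,
                           generate_dataset)

log = logging.getLogger("fundusiod")

TARGETS = ("mChT", "pChT")
NON_FEATURE_COLUMNS = ("mChT", "pChT", "al")


@dataclass
class PipelineConfig:
    """Configuration of one full run; fully serialized for provenance."""

    out_dir: str
    input_dir: str | None = None            # existing dataset; None -> synthesize
    synth: CohortParams = field(default_factory=CohortParams)
    image_size_px: int = 256
    camera_constant: float | None = None    # None -> nominal for image size
    seed: int = 0
    train_fraction: float = 0.70
    bin_width: float = DEFAULT_BIN_WIDTH
    k_max: int = 20
    target: str = "both"                    # "mChT" | "pChT" | "both"

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.target not in TARGETS + ("both",):
            raise ValueError(f"unknown target {self.target!r}")
        self.synth.validate()

    def targets(self) -> tuple[str, ...]:
        return TARGETS if self.target == "both" else (self.target,)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def extract_dataset_features(data_dir: str | Path,
                             camera_constant: float,
                             bin_width: float = DEFAULT_BIN_WIDTH
                             ) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Run geometry + radiomic extraction over every case of a dataset."""
    data_dir = Path(data_dir)
    subjects = pd.read_csv(data_dir / "subjects.csv").set_index("id")
    rows, units_out, flags_out = {}, {}, {}
    for cid, sub in subjects.iterrows():
        image, ann = case_io.load_case(data_dir / f"{cid}.png",
                                       data_dir / f"{cid}.json")
        mag = littmann_scale(float(sub["al"]), camera_constant)
        masks = build_roi_masks(ann, mag, image.shape[:2])
        features, units, flags = extract_pool(image, ann, masks, mag,
                                              bin_width)
        features["mChT"] = float(sub["mcht"])
        features["pChT"] = float(sub["pcht"])
        features["al"] = float(sub["al"])
        rows[cid] = features
        units_out.update(units)
        if flags:
            flags_out[cid] = flags
            log.warning("case %s flagged: %s", cid, flags)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "case_id"
    units_out.update({"mChT": "um", "pChT": "um", "al": "mm"})
    return FeatureTable(df, units_out), flags_out


def model_one_target(table: FeatureTable, target: str, train_ids, test_ids,
                     k_max: int) -> tuple[IODModel, SelectionPath, int,
                                          pd.DataFrame]:
    """Selection + fit + held-out evaluation for one ChT target."""
    df = table.data
    table.require_target(target)
    feat_cols = [c for c in df.columns if c not in NON_FEATURE_COLUMNS]
    usable = [c for c in feat_cols if df[c].notna().all()]
    train = df.loc[train_ids]
    test = df.loc[test_ids]
    path = lasso_order(train[usable], train[target].to_numpy(), k_max=k_max)
    k_star, selected = select_feature_count(
        path, train[usable], train[target].to_numpy(),
        test[usable], test[target].to_numpy())
    model = fit_iod(train, train[target].to_numpy(), selected, target)
    report = evaluate_iod(model, test)
    return model, path, k_star, report


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = (config.camera_constant if config.camera_constant is not None
          else camera_constant_for(config.image_size_px))
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.input_dir is None:
        data_dir = out / "data"
        generate_dataset(config.synth, data_dir,
                         image_size_px=config.image_size_px,
                         camera_constant=cc)
    else:
        data_dir = Path(config.input_dir)
    timings["synth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table, flags = extract_dataset_features(data_dir, cc, config.bin_width)
    case_io.write_feature_table(table, out / "features.csv")
    timings["extract"] = time.perf_counter() - t0

    if len(table.data) == 0:
        raise ValueError("zero eligible cases after extraction")

    train_ids, test_ids = split_cohort(table.data.index.to_numpy(),
                                       config.train_fraction, config.seed)
    summary: dict = {"n_cases": int(len(table.data)),
                     "n_train": int(len(train_ids)),
                     "n_test": int(len(test_ids)),
                     "flagged_cases": flags, "targets": {}}

    for target in config.targets():
        t0 = time.perf_counter()
        model, path, k_star, report = model_one_target(
            table, target, train_ids, test_ids, config.k_max)
        case_io.save_model(model, out / f"iod_{target}.json")
        path.to_frame().to_csv(out / f"selection_{target}.csv", index=False,
                               float_format="%.17g")
        report.to_csv(out / f"report_{target}.csv", float_format="%.17g")
        _plot_selection(path, k_star, out / f"selection_{target}.png", target)
        _plot_scatter(model, table.data.loc[test_ids],
                      out / f"scatter_{target}.png")
        summary["targets"][target] = {
            "k_star": int(k_star),
            "selected_features": model.feature_names,
            "test_spearman_r_vs_target": float(report.loc[target, "r"]),
            "test_linear_r2": float(report.attrs["target_linear_r2"]),
        }
        timings[f"model_{target}"] = time.perf_counter() - t0

    run_info = {"config": config.to_dict(), "package_version": __version__,
                "summary": summary}
    with open(out / "run.json", "w") as fh:
        json.dump(run_info, fh, indent=1, sort_keys=True, default=str)
    with open(out / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=1)
    return out


def _plot_selection(path: SelectionPath, k_star: int, out_path: Path,
                    target: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = np.arange(1, len(path.adj_r2_train) + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(k, path.adj_r2_train, "o-", label="training set", ms=3)
    ax.plot(k, path.adj_r2_test, "s-", label="test set", ms=3)
    ax.axvline(k_star, color="red", ls="--", lw=1, label=f"selected k={k_star}")
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("adjusted $R^2$")
    ax.set_title(f"feature-count selection ({target})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def _plot_scatter(model: IODModel, test: pd.DataFrame, out_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    iod = model.predict(test)
    y = test[model.target].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(iod, y, s=8, alpha=0.6)
    ax.set_xlabel(f"IOD_{model.target} (10 μm)")
    ax.set_ylabel(f"{model.target} (μm)")
    r2 = float(np.corrcoef(iod, y)[0, 1] ** 2) if len(y) > 1 else float("nan")
    ax.set_title(f"$R^2$ = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
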