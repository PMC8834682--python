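"""On-disk formats and run configuration.

Raw TCSPC histograms have no standard open interchange format (vendor
formats are proprietary binaries), so this package defines a plain-text one:

* a delimited table (default tab) with columns
  ``roi_id, condition, compartment, experiment, channel, time_ns, counts``,
  one row per (ROI, channel), counts integer;
* a YAML sidecar carrying the acquisition metadata
  (``<table>.meta.yaml`` by default).

Result tables (per-ROI metrics, pairwise comparisons) are tidy delimited
files with a ``#`` comment header documenting columns and units, rows in a
deterministic order.  The run configuration is a YAML document mapping onto
:class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyDatasetError, FormatError
from .simulate import CellTruth, ConditionDesign
from .tcspc import AcquisitionConfig, TCSPCHistogram

__all__ = [
    "HIST_COLUMNS",
    "RunConfig",
    "default_run_config",
    "read_run_config",
    "write_histograms",
    "read_histograms",
    "truths_table",
    "write_results",
]

HIST_COLUMNS = ["roi_id", "condition", "compartment", "experiment",
                "channel", "time_ns", "counts"]

_FORMAT_TAG = "flimfret-tcspc-v1"

#: Column documentation written as '#' comments at the top of result tables.
_TABLE_DOCS = {
    "metrics": [
        "per-ROI FLIM-FRET metrics",
        "tau_ud_ns / tau_qd_ns: fitted unquenched / quenched donor lifetimes [ns]",
        "efficiency_E: FLIM-FRET efficiency (fraction)",
        "apparent_E: apparent FRET efficiency (fraction)",
        "binding_pct: donor-acceptor binding ratio [%]",
        "distance_r_nm: donor-acceptor distance [nm]",
        "ad_ratio: acceptor:donor intensity ratio (dimensionless)",
        "qc_flags: semicolon-separated quality flags; flagged rows are",
        "excluded from group statistics",
    ],
    "comparisons": [
        "pairwise condition comparisons (Dunn post hoc on pooled ranks)",
        "H / omnibus_p: Kruskal-Wallis statistic and p-value for the metric",
        "z: Dunn z statistic; raw_p / adjusted_p: two-sided p before/after",
        "multiplicity correction; significant: adjusted_p < alpha",
    ],
    "fits": [
        "per-ROI fit log: one row per simulated or supplied ROI",
        "status: converged | flagged | failed; n_components: selected model",
        "tau_* [ns]; a_*_frac: donor-species amplitude fractions",
    ],
    "truths": [
        "generator ground truth per simulated cell",
        "true_tau_* [ns]; true_binding: bound-donor fraction;",
        "intensities in arbitrary units",
    ],
    "background": [
        "background gate vs the negative control",
        "threshold: control median; above_background: condition median above",
        "threshold AND Dunn-adjusted p < alpha",
    ],
}


# ---------------------------------------------------------------------------
# Histogram table + sidecar


def write_histograms(
    histograms: Sequence[TCSPCHistogram],
    table_path,
    meta_path=None,
    delimiter: str = "\t",
) -> None:
    """Write histograms as a delimited table plus a YAML metadata sidecar."""
    if not histograms:
        raise EmptyDatasetError("refusing to write an empty dataset")
    table_path = Path(table_path)
    meta_path = Path(meta_path) if meta_path else table_path.with_suffix(
        table_path.suffix + ".meta.yaml"
    )
    config = histograms[0].config
    if any(h.config != config for h in histograms):
        raise FormatError("all histograms in one dataset must share a config")

    frames = []
    t = config.channel_centers()
    for h in histograms:
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": h.roi_id,
                    "condition": h.condition,
                    "compartment": h.compartment,
                    "experiment": h.experiment_index,
                    "channel": np.arange(config.n_channels),
                    "time_ns": t,
                    "counts": h.counts,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(table_path, sep=delimiter, index=False, float_format="%.9g")
    meta = {"format": _FORMAT_TAG, "acquisition": config.to_dict(),
            "n_rois": len(histograms)}
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_histograms(
    table_path,
    meta_path=None,
    delimiter: str = "\t",
) -> list[TCSPCHistogram]:
    """Read a histogram dataset back; validates against the sidecar metadata."""
    table_path = Path(table_path)
    meta_path = Path(meta_path) if meta_path else table_path.with_suffix(
        table_path.suffix + ".meta.yaml"
    )
    if not meta_path.exists():
        raise FormatError(f"metadata sidecar not found: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    if not isinstance(meta, dict) or "acquisition" not in meta:
        raise FormatError(f"{meta_path}: missing 'acquisition' block")
    config = AcquisitionConfig.from_dict(meta["acquisition"])

    try:
        table = pd.read_csv(table_path, sep=delimiter, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{table_path}: dataset file is empty") from None
    if table.empty:
        raise EmptyDatasetError(f"{table_path}: dataset contains no rows")
    missing = [c for c in HIST_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{table_path}: missing columns {missing}")

    counts = table["counts"]
    bad = counts.isna() | (counts != np.floor(counts))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{table_path}: non-integer counts at row {row} "
            f"(roi_id={table['roi_id'].iloc[row]!r})"
        )

    out: list[TCSPCHistogram] = []
    for roi_id, grp in table.groupby("roi_id", sort=False):
        grp = grp.sort_values("channel")
        channels = grp["channel"].to_numpy()
        if len(channels) != config.n_channels or not np.array_equal(
            channels, np.arange(config.n_channels)
        ):
            raise FormatError(
                f"{table_path}: ROI {roi_id!r} has {len(channels)} channels, "
                f"metadata declares {config.n_channels}"
            )
        for col in ("condition", "compartment", "experiment"):
            if grp[col].nunique() > 1:
                raise FormatError(
                    f"{table_path}: ROI {roi_id!r} has inconsistent {col!r}"
                )
        out.append(
            TCSPCHistogram(
                counts=grp["counts"].to_numpy(dtype=np.int64),
                config=config,
                roi_id=str(roi_id),
                condition=str(grp["condition"].iloc[0]),
                compartment=str(grp["compartment"].iloc[0]),
                experiment_index=int(grp["experiment"].iloc[0]),
            )
        )
    return out


def truths_table(truths: Iterable[CellTruth]) -> pd.DataFrame:
    rows = [
        {
            "roi_id": t.roi_id,
            "condition": t.condition,
            "compartment": t.compartment,
            "experiment": t.experiment_index,
            "true_tau_ud": t.true_tau_ud,
            "true_tau_qd": t.true_tau_qd,
            "true_binding": t.true_binding,
            "photons": t.photons,
            "donor_intensity": t.donor_intensity,
            "acceptor_intensity": t.acceptor_intensity,
            "seed_used": t.seed_used,
        }
        for t in truths
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Result tables


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    delimiter: str = "\t",
) -> dict:
    """Write tidy result tables with documented headers; returns name->path.

    Rows are sorted deterministically (condition, roi_id where present);
    a comparisons table is re-validated (adjusted_p >= raw_p) at write time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        df = df.copy()
        sort_cols = [c for c in ("metric", "condition", "compartment", "roi_id",
                                 "group_a", "group_b") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols).reset_index(drop=True)
        if {"raw_p", "adjusted_p"} <= set(df.columns):
            if (df["adjusted_p"].to_numpy() < df["raw_p"].to_numpy() - 1e-12).any():
                raise FormatError(
                    f"table {name!r}: adjusted_p below raw_p; "
                    "refusing to write an inconsistent comparisons table"
                )
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            for line in _TABLE_DOCS.get(name, []):
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep=delimiter, index=False, float_format="%.9g")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything needed for one reproducible simulate->fit->stats run."""

    master_seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    designs: list = field(default_factory=list)
    objective: str = "poisson"
    model: str = "auto"  # auto | mono | biexp
    fix_tau_ud: Optional[float] = None
    delta_aic: float = 10.0
    runs_alpha: float = 0.05
    correction: str = "holm"
    alpha: float = 0.05
    negative_control: Optional[str] = "neg_ctrl_freeRuby"
    metrics: tuple = ("efficiency_E", "binding_pct", "apparent_E",
                      "distance_r_nm", "ad_ratio")
    r0_nm: float = 6.417
    output_dir: str = "flimfret_out"

    def __post_init__(self) -> None:
        keys = [(d.name, d.compartment) for d in self.designs]
        if len(set(keys)) != len(keys):
            raise ConfigError("duplicate condition (name, compartment) in designs")
        if self.model not in ("auto", "mono", "biexp"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.designs and self.negative_control is not None:
            if self.negative_control not in {d.name for d in self.designs}:
                raise ConfigError(
                    f"negative control {self.negative_control!r} "
                    "not among the designs"
                )

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "acquisition": self.acquisition.to_dict(),
            "designs": [
                {
                    k: getattr(d, k)
                    for k in (
                        "name", "tau_ud_mean", "tau_ud_sd", "tau_qd_mean",
                        "tau_qd_sd", "binding_mean", "binding_sd",
                        "photons_per_cell", "donor_intensity_logmean",
                        "donor_intensity_logsd", "acceptor_intensity_logmean",
                        "acceptor_intensity_logsd", "compartment", "n_cells",
                        "n_experiments", "ad_coupling",
                    )
                }
                for d in self.designs
            ],
            "fit": {
                "objective": self.objective,
                "model": self.model,
                "fix_tau_ud": self.fix_tau_ud,
                "delta_aic": self.delta_aic,
                "runs_alpha": self.runs_alpha,
            },
            "stats": {
                "correction": self.correction,
                "alpha": self.alpha,
                "negative_control": self.negative_control,
                "metrics": list(self.metrics),
            },
            "r0_nm": self.r0_nm,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()


def default_run_config(master_seed: int = 0, output_dir: str = "flimfret_out") -> RunConfig:
    from .simulate import paper_design

    return RunConfig(master_seed=master_seed, designs=paper_design(),
                     output_dir=output_dir)


def read_run_config(path) -> RunConfig:
    """Load a RunConfig from its YAML document."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    acq = AcquisitionConfig.from_dict(raw.get("acquisition", {}))
    designs = [ConditionDesign(**d) for d in raw.get("designs", [])]
    fit = raw.get("fit", {})
    stats = raw.get("stats", {})
    return RunConfig(
        master_seed=int(raw.get("master_seed", 0)),
        acquisition=acq,
        designs=designs,
        objective=fit.get("objective", "poisson"),
        model=fit.get("model", "auto"),
        fix_tau_ud=fit.get("fix_tau_ud"),
        delta_aic=float(fit.get("delta_aic", 10.0)),
        runs_alpha=float(fit.get("runs_alpha", 0.05)),
        correction=stats.get("correction", "holm"),
        alpha=float(stats.get("alpha", 0.05)),
        negative_control=stats.get("negative_control"),
        metrics=tuple(stats.get("metrics", ("efficiency_E", "binding_pct",
                                            "apparent_E", "distance_r_nm",
                                            "ad_ratio"))),
        r0_nm=float(raw.get("r0_nm", 6.417)),
        output_dir=str(raw.get("output_dir", "flimfret_out")),
    )
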