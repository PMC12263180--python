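"""OME-TIFF I/O, run configuration and the orchestrated pipeline.

The pipeline contract mirrors the analysis convention of the rest of the
package: thresholds are determined once per image *set* and applied to all
images; every output table echoes the thresholds and a hash of the
configuration so a run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import intensity as _intensity
from . import penetration as _penetration
from . import segmentation as _segmentation
from . import statmodel as _statmodel
from .errors import PipelineError, SpherostainError
from .synthgen import SpheroidImage


def write_ome_tiff(image: SpheroidImage, path) -> None:
    """Write a multi-channel image as OME-TIFF with named channels and µm pixel size."""
    names = list(image.channel_names)
    data = np.stack([image.channels[c] for c in names])
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_image(
    path,
    channel_names: list[str] | None = None,
    pixel_size: float | None = None,
) -> SpheroidImage:
    """Read a TIFF/OME-TIFF center-slice image.

    Channel names and pixel size come from OME metadata when present and
    may be overridden (and must be supplied for plain TIFF).
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        meta_names: list[str] | None = None
        meta_px: float | None = None
        if tf.ome_metadata:
            ome = tifffile.xml2dict(tf.ome_metadata).get("OME", {})
            img = ome.get("Image", {})
            if isinstance(img, list):
                img = img[0]
            pixels = img.get("Pixels", {})
            if "PhysicalSizeX" in pixels:
                meta_px = float(pixels["PhysicalSizeX"])
            ch = pixels.get("Channel", [])
            if isinstance(ch, dict):
                ch = [ch]
            names = [c.get("Name") for c in ch]
            if names and all(n is not None for n in names):
                meta_names = [str(n) for n in names]
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D multi-channel image, got shape {data.shape}")
    names = channel_names or meta_names
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for {data.shape[0]} channels in {path}"
        )
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ValueError(f"no pixel size in metadata of {path}; pass pixel_size")
    return SpheroidImage(channels={n: data[i] for i, n in enumerate(names)}, pixel_size=px)


@dataclass
class RunConfig:
    """Analysis configuration for one pipeline run."""

    #: channel name -> role (nuclear, nuclear_envelope, golgi, junction)
    channel_roles: dict[str, str] = field(
        default_factory=lambda: {
            "dapi": "nuclear",
            "lamin": "nuclear_envelope",
            "gm130": "golgi",
            "bcatenin": "junction",
        }
    )
    threshold_mode: str = "auto"  #: "auto" (pooled Otsu) or "fixed"
    fixed_thresholds: dict[str, float] | None = None
    background_mode: str = "inverse"
    #: per-channel background-mode overrides (e.g. lamin -> cytoplasm)
    background_overrides: dict[str, str] = field(default_factory=dict)
    closing_um: float = 5.0
    n_lines: int = 36
    rim_band_um: float = 5.0
    smoothing_window: int = 3
    pixel_size_override: float | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if "nuclear" not in self.channel_roles.values():
            raise ValueError("one channel must have the 'nuclear' role")

    @property
    def nuclear_channel(self) -> str:
        return next(c for c, r in self.channel_roles.items() if r == "nuclear")

    @property
    def junction_channel(self) -> str | None:
        return next((c for c, r in self.channel_roles.items() if r == "junction"), None)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(
    images: list[tuple[str, SpheroidImage]],
    config: RunConfig,
    times: dict[str, float] | None = None,
    groups: dict[str, str] | None = None,
    geometry: dict[str, tuple[float, float, float]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Segment, quantify and profile a set of spheroid images.

    ``images`` is a list of ``(spheroid_id, image)``.  Optional mappings
    attach a staining time (-> time-course regression of fractional
    penetration) or a group label (-> per-channel two-group comparison of
    intensity) to each spheroid id.  ``geometry`` may supply known
    ``(center_x, center_y, radius)`` per id (e.g. from a simulation
    ground-truth table); otherwise geometry comes from segmentation.
    Deterministic given images and config.
    """
    if not images:
        raise ValueError("need at least one image")
    thresholds = _segmentation.determine_thresholds(
        [img for _, img in images], mode=config.threshold_mode, fixed=config.fixed_thresholds
    )
    chash = config.config_hash()
    seg_rows, int_rows, pen_rows = [], [], []
    measured: dict[str, dict[str, float]] = {}
    for sid, img in images:
        try:
            seg = _segmentation.segment_image(
                img, thresholds,
                nuclear_channel=config.nuclear_channel,
                closing_um=config.closing_um,
            )
            seg_rows.append(
                {
                    "spheroid_id": sid,
                    "center_x_um": seg.center[0],
                    "center_y_um": seg.center[1],
                    "area_px": seg.area_px,
                    "area_um2": seg.area_um2,
                    "equivalent_diameter_um": seg.equivalent_diameter_um,
                }
            )
            for c in img.channel_names:
                if c not in thresholds:
                    continue
                mode = config.background_overrides.get(c, config.background_mode)
                st = _intensity.compute_stats(img, c, seg, background_mode=mode)
                int_rows.append(
                    {
                        "spheroid_id": sid,
                        "channel": c,
                        "threshold": thresholds[c],
                        "mean_background": st.mean_background,
                        "positive_pixels": st.positive_pixel_count,
                        "spheroid_area_px": st.spheroid_area_px,
                        "mean_intensity": st.mean_intensity,
                        "total_normalized_intensity": st.total_normalized_intensity,
                        "background_mode": mode,
                    }
                )
            jc = config.junction_channel
            if jc is not None and jc in img.channel_names:
                if geometry is not None and sid in geometry:
                    gx, gy, gr = geometry[sid]
                    pres = _penetration.measure_penetration(
                        img, jc, center_um=(gx, gy), radius_um=gr,
                        n_lines=config.n_lines, rim_band_um=config.rim_band_um,
                        smoothing_window=config.smoothing_window,
                    )
                else:
                    pres = _penetration.measure_penetration(
                        img, jc, seg=seg,
                        n_lines=config.n_lines, rim_band_um=config.rim_band_um,
                        smoothing_window=config.smoothing_window,
                    )
                pen_rows.append(
                    {
                        "spheroid_id": sid,
                        "channel": jc,
                        "n_lines": pres.n_lines_used,
                        "mean_depth_um": pres.mean_depth_um,
                        "sd_depth_um": pres.sd_depth_um,
                        "fractional_depth": pres.fractional_depth,
                        "complete": pres.complete,
                        "rim_mean": pres.rim_mean,
                    }
                )
                measured[sid] = {"fractional_depth": pres.fractional_depth}
        except SpherostainError as exc:
            raise PipelineError(sid, str(exc)) from exc

    for rows in (seg_rows, int_rows, pen_rows):
        for r in rows:
            r["config_hash"] = chash
    out = {
        "segmentation": pd.DataFrame(seg_rows),
        "intensity": pd.DataFrame(int_rows),
        "penetration": pd.DataFrame(pen_rows),
    }

    if times is not None and pen_rows:
        tt, yy = [], []
        for sid, m in measured.items():
            if sid in times:
                tt.append(times[sid])
                yy.append(m["fractional_depth"])
        fit = _statmodel.fit_timecourse(tt, yy)
        row = dataclasses.asdict(fit)
        try:
            row["predicted_complete_time_min"] = _statmodel.predict_complete_time(fit)
        except ValueError:
            row["predicted_complete_time_min"] = float("nan")
        row["response"] = "fractional_depth"
        row["config_hash"] = chash
        out["timecourse"] = pd.DataFrame([row])

    if groups is not None:
        labels = sorted(set(groups.values()))
        if len(labels) != 2:
            raise ValueError("group comparison requires exactly two group labels")
        cmp_rows = []
        idf = out["intensity"]
        for c in sorted(idf["channel"].unique()):
            sub = idf[idf["channel"] == c]
            vals = {
                lab: sub[sub["spheroid_id"].map(groups) == lab][
                    "total_normalized_intensity"
                ].to_numpy()
                for lab in labels
            }
            res = _statmodel.compare_groups(vals[labels[0]], vals[labels[1]], alpha=config.alpha)
            cmp_rows.append(
                {
                    "channel": c,
                    "statistic": "total_normalized_intensity",
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "test_used": res.test_used,
                    "f_statistic": res.f_statistic,
                    "f_p_value": res.f_p_value,
                    "t_statistic": res.t_statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "stars": res.stars,
                    "mean_a": res.group_means[0],
                    "mean_b": res.group_means[1],
                    "sd_a": res.group_sds[0],
                    "sd_b": res.group_sds[1],
                    "n_a": res.n_per_group[0],
                    "n_b": res.n_per_group[1],
                    "config_hash": chash,
                }
            )
        out["comparison"] = pd.DataFrame(cmp_rows)

    thr_df = pd.DataFrame(
        [{"channel": c, "threshold": t, "config_hash": chash} for c, t in thresholds.items()]
    )
    out["thresholds"] = thr_df
    return out


def write_results(results: dict[str, pd.DataFrame], outdir) -> list[Path]:
    """Write every result table as CSV in ``outdir`` (no timestamps, so reruns are byte-identical)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
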