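"""Readers/writers for the text formats the pipeline speaks, plus the
all-in-one configured run.

All interval files are 0-based half-open (BED convention). Every writer
emits a provenance header (# key=value comment lines for TSV/bedGraph, a
"provenance" block in JSON); timestamps are deliberately excluded so that
identical configs produce byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .cnprofile import (
    BinTrack,
    SegmentSet,
    call_copy_numbers,
    compute_ratio_profile,
    correct_gc_bias,
    segment_profile,
)
from .baseline import (
    ClassifierConfig,
    affected_chromosomes,
    classify_loci,
    estimate_dispersion,
    pair_profiles,
    summarize,
)
from .genome import toy_genome
from .simulate import ReadDepthParams, simulate_bin_counts, simulate_cn_profiles
from .tracking import MovieStack

logger = logging.getLogger(__name__)


def provenance_block(params: Mapping[str, Any]) -> dict[str, Any]:
    return {"tool": "cinmetrics", "version": __version__, "params": dict(params)}


def _provenance_lines(params: Mapping[str, Any]) -> list[str]:
    block = provenance_block(params)
    flat = {"tool": block["tool"], "version": block["version"], **block["params"]}
    return [f"# {k}={v}" for k, v in flat.items()]


# ---------------------------------------------------------------------------
# bin tracks


def read_bin_track(path: str | Path) -> BinTrack:
    """Read a bedGraph (chrom start end count) or BED-like TSV with an
    optional 5th GC column. Malformed lines are reported by number."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                count = float(fields[3])
                gc = float(fields[4]) if len(fields) == 5 else np.nan
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            rows.append((lineno, chrom, start, end, gc, count))
    if not rows:
        raise ValueError(f"{path}: no data lines")
    df = pd.DataFrame(rows, columns=["lineno", "chrom", "start", "end", "gc", "count"])
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        linenos = sub["lineno"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"{path}: bins overlap or are unsorted on {chrom} "
                f"(lines {linenos[i]} and {linenos[i + 1]})"
            )
    return BinTrack(df.drop(columns="lineno").reset_index(drop=True))


def write_bin_track(track: BinTrack, path: str | Path, params: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    df = track.bins
    with path.open("w") as fh:
        for line in _provenance_lines(params or {}):
            fh.write(line + "\n")
        for row in df.itertuples(index=False):
            gc = "" if pd.isna(row.gc) else f"\t{row.gc:.6f}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.count:.6f}{gc}\n")


def write_bedgraph(
    df: pd.DataFrame, value_col: str, path: str | Path, params: Mapping[str, Any] | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(params or {}):
            fh.write(line + "\n")
        for row in df.itertuples(index=False):
            value = getattr(row, value_col)
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# segments


def read_segments(path: str | Path) -> SegmentSet:
    """BED-like TSV: chrom start end n_bins mean_log2 [cn]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected >= 5 columns (chrom start end n_bins mean_log2)")
    names = ["chrom", "start", "end", "n_bins", "mean_log2"]
    if df.shape[1] >= 6:
        names.append("cn")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return SegmentSet(segments=df)


def write_segments(
    segments: SegmentSet, path: str | Path, params: Mapping[str, Any] | None = None
) -> None:
    path = Path(path)
    df = segments.segments
    with path.open("w") as fh:
        for line in _provenance_lines(params or {}):
            fh.write(line + "\n")
        for row in df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end), str(row.n_bins), f"{row.mean_log2:.6f}"]
            if hasattr(row, "cn"):
                fields.append(str(row.cn))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# tables and movies


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str | Path, params: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _provenance_lines(params or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_movie(
    path: str | Path, pixel_size_um: float | None, frame_interval_s: float | None
) -> MovieStack:
    """Multi-page TIFF -> MovieStack. Pixel size and frame interval must be
    supplied explicitly; there is no metadata guessing."""
    if pixel_size_um is None:
        raise ValueError("pixel size is required (e.g. --pixel-size 0.1)")
    if frame_interval_s is None:
        raise ValueError("frame interval is required (e.g. --interval 2)")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    return MovieStack(
        data=np.asarray(data), pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s
    )


def write_movie(stack: MovieStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.data)


def write_json(obj: dict, path: str | Path, params: Mapping[str, Any] | None = None) -> None:
    payload = dict(obj)
    payload["provenance"] = provenance_block(params or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# configured end-to-end run


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "simulate": {
        "n_alterations": 10,
        "attenuation_fraction": 0.7,
        "new_alteration_fraction": 0.3,
        "alteration_length": 20_000_000,
    },
    "depth": {"mean_count": 100.0, "dispersion": 0.05, "gc_linear": 0.3, "gc_quad": -0.5},
    "profile": {"ploidy": 2, "min_bins": 3, "alpha": 0.01},
    "compare": {"dispersion_estimator": "mad", "sign_flip": "further", "min_changed_fraction": 0.1},
}


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """simulate -> counts -> profile -> segment -> compare, writing every
    intermediate plus a summary JSON. Deterministic for a fixed config."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    ploidy = int(cfg["profile"]["ploidy"])
    genome = toy_genome(ploidy=ploidy)

    sim = cfg["simulate"]
    control_truth, kd_truth, truth = simulate_cn_profiles(
        genome,
        n_alterations=int(sim["n_alterations"]),
        attenuation_fraction=float(sim["attenuation_fraction"]),
        new_alteration_fraction=float(sim["new_alteration_fraction"]),
        seed=seed,
        alteration_length=int(sim["alteration_length"]),
    )
    depth = cfg["depth"]
    seg_by_condition: dict[str, SegmentSet] = {}
    profiles = {}
    for offset, (label, true_profile) in enumerate(
        [("control", control_truth), ("knockdown", kd_truth)]
    ):
        params = ReadDepthParams(
            mean_count=float(depth["mean_count"]),
            dispersion=float(depth["dispersion"]),
            gc_linear=float(depth["gc_linear"]),
            gc_quad=float(depth["gc_quad"]),
            seed=seed + 1000 * (offset + 1),
        )
        track = simulate_bin_counts(true_profile, genome, params)
        write_bin_track(track, out / f"{label}.bins.tsv", {"stage": "simulate", "condition": label, "seed": params.seed})
        corrected = correct_gc_bias(track)
        profile = compute_ratio_profile(corrected)
        segments = segment_profile(
            profile,
            min_bins=int(cfg["profile"]["min_bins"]),
            alpha=float(cfg["profile"]["alpha"]),
            seed=seed + 10 * (offset + 1),
        )
        segments = call_copy_numbers(segments, ploidy=ploidy)
        write_segments(segments, out / f"{label}.segments.tsv", {"stage": "profile", "condition": label})
        seg_by_condition[label] = segments
        profiles[label] = profile

    cmp_cfg = cfg["compare"]
    dispersion = estimate_dispersion(
        profiles["control"],
        segments=seg_by_condition["control"],
        estimator=cmp_cfg["dispersion_estimator"],
    )
    config_cls = ClassifierConfig(
        half_width=2.0 * dispersion,
        dispersion_estimator=cmp_cfg["dispersion_estimator"],
        sign_flip=cmp_cfg["sign_flip"],
    )
    paired = pair_profiles(seg_by_condition["control"], seg_by_condition["knockdown"])
    classification = classify_loci(paired, config_cls)
    summary = summarize(classification)
    affected = affected_chromosomes(
        classification, min_changed_fraction=float(cmp_cfg["min_changed_fraction"])
    )
    write_table(
        classification.loci,
        out / "classification.tsv",
        {"stage": "compare", "half_width": f"{config_cls.half_width:.6g}"},
    )
    result = {
        "summary": summary.to_dict(),
        "affected_chromosomes": affected,
        "half_width": config_cls.half_width,
        "dispersion": dispersion,
        "ground_truth": {
            "closer_bp": truth.closer_bp,
            "further_bp": truth.further_bp,
            "altered_bp_control": truth.altered_bp_control,
        },
    }
    write_json(result, out / "summary.json", {"stage": "compare", "seed": seed})
    return result
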