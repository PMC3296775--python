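"""Readers and writers for the pipeline's tab-delimited formats.

Internal coordinates are 0-based half-open everywhere, so sizes are always
``end - start``. SEG files follow the community convention of 1-based
inclusive coordinates; BED files are 0-based half-open. All round trips
between the three conventions are lossless.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import ProbePanel
from .regions import DifferentialRegion
from .segmentation import GAIN, LOSS, NEUTRAL, Segment, SegmentProfile
from .states import FrequencyTrack, StateMatrix

__all__ = [
    "SegFormatError",
    "read_seg",
    "write_seg",
    "read_profiles",
    "write_profiles",
    "read_annotations",
    "write_annotations",
    "write_bed",
    "read_bed",
    "write_regions_table",
    "write_state_matrix",
    "write_frequency_track",
]

log = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chromosome", "loc.start", "loc.end", "num.mark", "seg.mean"]


class SegFormatError(ValueError):
    pass


def write_seg(profiles, path) -> None:
    """Write segment profiles as SEG (1-based inclusive) plus a state column."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS + ["state"]) + "\n")
        for prof in profiles:
            for s in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{s.chrom}\t{s.start_bp + 1}\t{s.end_bp}"
                    f"\t{s.n_markers}\t{s.mean_logratio:.6g}\t{s.state}\n"
                )


def read_seg(path) -> list[SegmentProfile]:
    """Read a SEG file into segment profiles (internal half-open coords).

    Plain 6-column SEG is accepted; states are then inferred from the sign
    of the segment mean (logged, since the deviation test is skipped).
    Unsorted or overlapping rows within a sample raise with the line number.
    """
    profiles: dict[str, SegmentProfile] = {}
    last: dict[tuple, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6:
            raise SegFormatError("SEG header must have at least 6 tab-delimited columns")
        has_state = len(header) >= 7 and header[6] == "state"
        if not has_state:
            log.warning("no state column in %s; inferring state from seg.mean sign", path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise SegFormatError(f"line {lineno}: expected >= 6 columns")
            sid, chrom = parts[0], parts[1]
            try:
                start = int(parts[2]) - 1  # 1-based inclusive -> half-open
                end = int(parts[3])
                n_mark = int(parts[4])
                mean = float(parts[5])
            except ValueError as exc:
                raise SegFormatError(f"line {lineno}: {exc}") from exc
            if has_state:
                state = parts[6]
            else:
                state = GAIN if mean > 0 else LOSS if mean < 0 else NEUTRAL
            key = (sid, chrom)
            if key in last and start < last[key]:
                raise SegFormatError(
                    f"line {lineno}: unsorted or overlapping segment for sample {sid} on {chrom}"
                )
            last[key] = end
            profiles.setdefault(sid, SegmentProfile(sample_id=sid)).segments.append(
                Segment(chrom=chrom, start_bp=start, end_bp=end,
                        n_markers=n_mark, mean_logratio=mean, state=state)
            )
    return list(profiles.values())


def write_profiles(panel: ProbePanel, profiles: pd.DataFrame, path) -> None:
    """Probe x sample log-ratio matrix with chrom/pos/probe_id key columns."""
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos, "probe_id": panel.probe_id})
    df = pd.concat([df, profiles.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profiles(path) -> tuple[ProbePanel, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "probe_id"):
        if col not in df.columns:
            raise ValueError(f"profile matrix missing column {col!r}")
    panel = ProbePanel(df["chrom"].to_numpy(object), df["pos"].to_numpy(np.int64),
                       df["probe_id"].to_numpy(object))
    samples = [c for c in df.columns if c not in ("chrom", "pos", "probe_id")]
    return panel, df[samples].astype(float)


ANNOTATION_COLUMNS = [
    "sample_id", "group", "gender", "age", "stage", "race", "egfr", "kras", "pack_years",
]


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("annotation table must have a sample_id column")
    return df


def write_bed(regions, path) -> None:
    """Write regions/MCRs as 0-based half-open BED with status in the name.

    Columns: chrom, start, end, name (``etype_group``), score (the exact p
    where available, else '.'). Ordering is deterministic by (chrom, start).
    """
    recs = sorted(regions, key=lambda r: (str(r.chrom), int(r.start), int(r.end)))
    with open(path, "w") as fh:
        for r in recs:
            p = getattr(r, "p", None)
            score = f"{p:.6g}" if p is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.status}\t{score}\n")


def read_bed(path) -> list[DifferentialRegion]:
    """Read a status BED back into region records (etype/group from name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            etype, group = GAIN, ""
            if len(parts) > 3 and "_" in parts[3]:
                etype, group = parts[3].split("_", 1)
            p = float(parts[4]) if len(parts) > 4 and parts[4] != "." else float("nan")
            out.append(
                DifferentialRegion(chrom=chrom, start=start, end=end, etype=etype,
                                   group=group, freq_a=float("nan"), freq_b=float("nan"), p=p)
            )
    return out


def write_regions_table(regions, path) -> None:
    """Region table mirroring a publication-style MCR listing.

    Columns: Region, Cytoband (blank unless supplied), Chr, Start, End,
    Size (= End - Start), Status.
    """
    with open(path, "w") as fh:
        fh.write("Region\tCytoband\tChr\tStart\tEnd\tSize\tStatus\n")
        for i, r in enumerate(sorted(regions, key=lambda r: (str(r.chrom), int(r.start))), 1):
            cytoband = getattr(r, "cytoband", "")
            fh.write(
                f"R{i}\t{cytoband}\t{r.chrom}\t{r.start}\t{r.end}\t{r.end - r.start}\t{r.status}\n"
            )


def write_state_matrix(matrix: StateMatrix, path) -> None:
    """BED-like export: chrom, start, end, then one state column per sample."""
    df = pd.DataFrame({
        "chrom": matrix.grid.chrom,
        "start": matrix.grid.start,
        "end": matrix.grid.end,
    })
    for j, sid in enumerate(matrix.samples):
        df[sid] = matrix.states[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_frequency_track(track: FrequencyTrack, panel: ProbePanel, path) -> None:
    """bedGraph-like export of the gain/loss/any frequency landscape."""
    df = pd.DataFrame({
        "chrom": panel.chrom,
        "pos": panel.pos,
        "gain": track.gain,
        "loss": track.loss,
        "any": track.any_alteration,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
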