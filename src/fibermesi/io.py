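"""Readers, writers, and run configuration.

MESI stacks are multi-page grayscale TIFFs ordered as repeated sequences,
one page per exposure (shortest first within a sequence).  A sidecar CSV
(``page_index, exposure_s, sequence_index``) maps pages to exposures; the
exposure time is also written into each page's description for portability,
but the sidecar wins on conflict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, InputError
from .speckle import ExposureLadder

__all__ = ["MESISequence", "RunConfig", "write_sequence_stack", "read_sequence_stack"]


@dataclass
class MESISequence:
    """Raw frames of one MESI sequence, shortest exposure first."""

    ladder: ExposureLadder
    frames: list[np.ndarray]
    sequence_index: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) != self.ladder.count:
            raise InputError(
                f"{len(self.frames)} frames for a {self.ladder.count}-exposure ladder"
            )
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise InputError("all frames in a sequence must share one shape")


@dataclass
class RunConfig:
    """Analysis configuration with the protocol's default values.

    Defaults: 15-exposure 50 us - 80 ms ladder, 7x7 contrast window, 36
    nearest fibers, 1500 1/s occlusion threshold with 60 s clearance
    persistence, 0.3 s sequence period.
    """

    ladder_times: list[float] = field(
        default_factory=lambda: list(ExposureLadder.default().times)
    )
    raw_stack: Optional[str] = None
    flatfield: Optional[str] = None
    output_dir: str = "."
    radius_range: tuple[float, float] = (4.0, 8.0)
    sensitivity: float = 0.5
    k_neighbors: int = 36
    window: int = 7
    rois: dict = field(default_factory=dict)
    occlusion_threshold: float = 1500.0
    persistence_s: float = 60.0
    sequence_period_s: float = 0.3
    seed: int = 0

    @property
    def ladder(self) -> ExposureLadder:
        return ExposureLadder(self.ladder_times)

    def to_yaml(self, path) -> None:
        d = {
            "ladder_times": list(self.ladder_times),
            "raw_stack": self.raw_stack,
            "flatfield": self.flatfield,
            "output_dir": self.output_dir,
            "radius_range": list(self.radius_range),
            "sensitivity": self.sensitivity,
            "k_neighbors": self.k_neighbors,
            "window": self.window,
            "rois": self.rois,
            "occlusion_threshold": self.occlusion_threshold,
            "persistence_s": self.persistence_s,
            "sequence_period_s": self.sequence_period_s,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "radius_range" in d:
            d["radius_range"] = tuple(d["radius_range"])
        return cls(**d)


def write_sequence_stack(
    path,
    sequences: Sequence[MESISequence],
    sidecar_path=None,
) -> None:
    """Write sequences as a multi-page float32 TIFF plus a sidecar CSV."""
    if len(sequences) == 0:
        raise InputError("nothing to write")
    ladder = sequences[0].ladder
    rows = []
    page = 0
    with tifffile.TiffWriter(path) as tif:
        for s_i, seq in enumerate(sequences):
            if seq.ladder.times != ladder.times:
                raise InputError("all sequences must share one exposure ladder")
            for T, frame in zip(ladder.times, seq.frames):
                tif.write(
                    np.asarray(frame, dtype=np.float32),
                    description=json.dumps({"exposure_s": T, "sequence_index": s_i}),
                    contiguous=False,
                )
                rows.append((page, T, s_i))
                page += 1
    if sidecar_path is not None:
        pd.DataFrame(
            rows, columns=["page_index", "exposure_s", "sequence_index"]
        ).to_csv(sidecar_path, index=False)


def read_sequence_stack(
    path,
    sidecar=None,
    ladder: Optional[ExposureLadder] = None,
) -> list[MESISequence]:
    """Read a MESI stack back into sequences, shortest exposure first.

    With a sidecar CSV, pages are grouped by its ``sequence_index`` and
    ordered by ``exposure_s``.  Without one, a ladder must be given and the
    page count must divide evenly into sequences of ``ladder.count`` pages
    in acquisition order.
    """
    # enumerate pages explicitly: per-page descriptions can split the file
    # into multiple series, and plain imread would return only the first
    with tifffile.TiffFile(path) as tif:
        pages = np.stack([p.asarray() for p in tif.pages])
    n_pages = pages.shape[0]

    if sidecar is not None:
        df = pd.read_csv(sidecar, float_precision="round_trip")
        required = {"page_index", "exposure_s", "sequence_index"}
        if not required.issubset(df.columns):
            raise FormatError(f"sidecar must have columns {sorted(required)}")
        if len(df) != n_pages:
            raise FormatError(
                f"sidecar lists {len(df)} pages, stack has {n_pages}"
            )
        sequences = []
        for s_i, grp in df.groupby("sequence_index"):
            grp = grp.sort_values("exposure_s")
            lad = ExposureLadder(grp["exposure_s"].to_numpy())
            frames = [pages[int(p)].astype(float) for p in grp["page_index"]]
            sequences.append(MESISequence(lad, frames, sequence_index=int(s_i)))
        sequences.sort(key=lambda s: s.sequence_index)
        return sequences

    if ladder is None:
        raise FormatError("either a sidecar or an exposure ladder is required")
    n_exp = ladder.count
    if n_pages % n_exp != 0:
        raise FormatError(
            f"stack has {n_pages} pages, not divisible by the "
            f"{n_exp}-exposure ladder"
        )
    sequences = []
    for s_i in range(n_pages // n_exp):
        frames = [pages[s_i * n_exp + j].astype(float) for j in range(n_exp)]
        sequences.append(MESISequence(ladder, frames, sequence_index=s_i))
    return sequences
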