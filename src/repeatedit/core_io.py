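"""Readers, writers and run configuration.

External formats handled here: FASTQ (plain or gzip), GeneMapper-style
peak tables (TSV: size, height), per-position pileup count tables (TSV:
locus, position, A, C, G, T, depth), key=value run-config files, and the
TSV/JSON reports every pipeline stage emits.  All tabular outputs carry a
commented provenance header (tool version, seed, config hash).
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .instability import PeakTrace

__all__ = [
    "RunConfig",
    "read_fastq",
    "read_peak_table",
    "read_pileup",
    "write_table",
    "write_json_report",
]


@dataclass
class RunConfig:
    """One run's parameters; serializes losslessly to a key=value file."""

    locus_name: str = "locus"
    repeat_spec: str = "cag-cbe"
    peak_height_fraction: float = 0.05
    detection_threshold: float = 0.005
    substantial_threshold: float = 0.05
    min_coverage: int = 30
    contraction_cap: int = 40
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("peak_height_fraction", "detection_threshold",
                     "substantial_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_coverage < 0:
            raise ValueError("min_coverage must be >= 0")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            caster = {"int": int, "float": float, "str": str}[str(types[key])]
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def digest(self) -> str:
        """Short stable hash of the configuration, for report headers."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, bases, qualities)`` from a 4-line-record FASTQ.

    Bases are uppercased.  A record whose quality string length differs
    from its sequence length is rejected with the (0-based) record index.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):  # pragma: no cover - biopython raises first
                    raise ValueError("length mismatch")
                yield title.split()[0] if title else "", seq.upper(), qual
                index += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {index}: {exc}") from exc


def read_peak_table(
    path: str | Path,
    flank_bp: float | None = None,
    unit_length: int = 3,
    label: str = "",
) -> PeakTrace:
    """Read a (size, height) TSV into a :class:`PeakTrace`.

    When ``flank_bp`` is given, fragment sizes in nt are converted to
    repeat units via ``(size - flank_bp) / unit_length``; amplicons differ
    in flank length between assays, so no constant is assumed.  Duplicate
    sizes are summed and peaks are returned sorted ascending by size.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"size", "height"} <= set(df.columns):
        raise ValueError("peak table must have columns: size, height")
    if (df["height"] < 0).any():
        bad = df.index[df["height"] < 0][0]
        raise ValueError(f"negative peak height at row {bad}")
    sizes = df["size"].astype(float)
    if flank_bp is not None:
        sizes = (sizes - flank_bp) / unit_length
    merged = (
        pd.DataFrame({"size": sizes, "height": df["height"].astype(float)})
        .groupby("size", as_index=False)["height"].sum()
        .sort_values("size")
    )
    peaks = list(zip(merged["size"], merged["height"]))
    return PeakTrace(peaks=peaks, label=label or Path(path).stem)


_PILEUP_COLS = ["locus", "position", "A", "C", "G", "T", "depth"]


def read_pileup(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a per-position base-count table, grouped by locus.

    Enforces ``depth == A + C + G + T`` at every position and unique
    positions within a locus; per-locus row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PILEUP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    sums = df[["A", "C", "G", "T"]].sum(axis=1)
    bad = df.index[sums != df["depth"]]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"depth mismatch at locus {row['locus']} position {row['position']}: "
            f"depth={row['depth']} but base counts sum to {sums[bad[0]]}"
        )
    out: dict[str, pd.DataFrame] = {}
    for locus, group in df.groupby("locus", sort=False):
        if group["position"].duplicated().any():
            raise ValueError(f"duplicate position within locus {locus}")
        out[str(locus)] = group.reset_index(drop=True)
    return out


def provenance_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    parts = [f"repeatedit {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config={config.digest()}")
    return "# " + "\t".join(parts)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a TSV report with a commented provenance header line."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json_report(
    payload: dict,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    meta = {"tool": f"repeatedit {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config"] = config.digest()
    Path(path).write_text(
        json.dumps({"provenance": meta, **payload}, indent=2, sort_keys=True) + "\n"
    )


def write_peak_table(trace: PeakTrace, path: str | Path) -> None:
    """Writer matching :func:`read_peak_table` (repeat-unit scale)."""
    df = pd.DataFrame(trace.peaks, columns=["size", "height"])
    df.to_csv(path, sep="\t", index=False)


def write_pileup(groups: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Writer matching :func:`read_pileup`."""
    df = pd.concat(groups.values(), ignore_index=True)
    df[_PILEUP_COLS].to_csv(path, sep="\t", index=False)
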