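"""Readers and writers for the package's plain-text formats.

* land / region rasters: ASCII grids with a three-line header
  (``rows N`` / ``cols M`` / ``cellsize_km X``) followed by 0/1 rows
  (0 = sea);
* sampling schemes: TSV with the columns ``sample_id row col generation
  layer n group_id`` (0-based grid indices and generations);
* sequences: FASTA (via Biopython) with the population sample in the
  record description, supporting an HVS-I-style coordinate window and a
  site-exclusion mask on reading; and an Arlequin-style haplotype list
  (haplotype string + count per group);
* summary statistics and reference tables: TSV;
* configuration: TOML; run manifests: JSON (config snapshot, seeds,
  package versions and input hashes, enough to reproduce a run bit for
  bit).
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import SCHEME_COLUMNS, HaplotypeSample, SamplingScheme

__all__ = [
    "read_raster",
    "write_raster",
    "read_scheme",
    "write_scheme",
    "read_fasta_samples",
    "write_fasta_samples",
    "read_haplotype_list",
    "write_haplotype_list",
    "write_stats_tsv",
    "read_reference_table",
    "write_reference_table",
    "read_config",
    "write_config",
    "RunManifest",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------


def read_raster(path) -> tuple[np.ndarray, float]:
    """Read an ASCII 0/1 raster; returns (boolean mask, cellsize_km)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    body_start = 0
    for i, line in enumerate(lines[:3]):
        try:
            key, value = line.split()
        except ValueError as err:
            raise FormatError(f"{path}:{i + 1}: malformed header line {line!r}") from err
        header[key] = float(value)
        body_start = i + 1
    for key in ("rows", "cols", "cellsize_km"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key!r}")
    rows, cols = int(header["rows"]), int(header["cols"])
    body = [l for l in lines[body_start:] if l.strip()]
    if len(body) != rows:
        raise FormatError(f"{path}: expected {rows} raster rows, found {len(body)}")
    grid = np.zeros((rows, cols), dtype=bool)
    for r, line in enumerate(body):
        vals = line.split()
        if len(vals) != cols:
            raise FormatError(
                f"{path}:{body_start + r + 1}: expected {cols} columns, found {len(vals)}"
            )
        if any(v not in ("0", "1") for v in vals):
            raise FormatError(f"{path}:{body_start + r + 1}: raster values must be 0/1")
        grid[r] = [v == "1" for v in vals]
    return grid, header["cellsize_km"]


def write_raster(path, mask: np.ndarray, cellsize_km: float = 100.0) -> None:
    mask = np.asarray(mask).astype(int)
    with open(path, "w") as fh:
        fh.write(f"rows {mask.shape[0]}\ncols {mask.shape[1]}\n")
        fh.write(f"cellsize_km {cellsize_km:g}\n")
        for row in mask:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sampling schemes
# ---------------------------------------------------------------------------

_SCHEME_HEADER = (
    "# sampling scheme: 0-based (row, col) grid indices; generations 0-based "
    "from simulation start\n"
)


def read_scheme(path) -> SamplingScheme:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SCHEME_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: scheme missing columns {missing}")
    return SamplingScheme(table)


def write_scheme(path, scheme: SamplingScheme) -> None:
    with open(path, "w") as fh:
        fh.write(_SCHEME_HEADER)
        scheme.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def write_fasta_samples(path, samples: Sequence[HaplotypeSample]) -> None:
    """One record per lineage; the population sample goes in the
    description (``group=<id>``)."""
    records = []
    for s in samples:
        for seq, sid in zip(s.sequences, s.ids):
            records.append(
                SeqRecord(Seq(seq), id=str(sid), description=f"group={s.group_id}")
            )
    SeqIO.write(records, path, "fasta")


def read_fasta_samples(
    path,
    window: Optional[tuple[int, int]] = None,
    window_origin: int = 1,
    exclude_positions: Sequence[int] = (),
    default_group: str = "all",
) -> list[HaplotypeSample]:
    """Read aligned FASTA into one HaplotypeSample per ``group=`` tag.

    ``window=(start, end)`` cuts every sequence to a coordinate window
    (inclusive, in the coordinate system starting at ``window_origin`` for
    the first alignment column — e.g. ``window=(16051, 16400),
    window_origin=16024`` for an HVS-I alignment).  ``exclude_positions``
    drops single sites (same coordinates), e.g. the 16189 C-stretch.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        return []
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"{path}: mixed-length records {sorted(lengths)}")
    L = lengths.pop()
    keep = np.ones(L, dtype=bool)
    if window is not None:
        start, end = window
        idx = np.arange(window_origin, window_origin + L)
        keep &= (idx >= start) & (idx <= end)
    if len(list(exclude_positions)):
        idx = np.arange(window_origin, window_origin + L)
        keep &= ~np.isin(idx, list(exclude_positions))
    groups: dict[str, tuple[list, list]] = {}
    for r in records:
        group = default_group
        for tok in r.description.split():
            if tok.startswith("group="):
                group = tok[len("group="):]
        seq = "".join(np.array(list(str(r.seq).upper()))[keep])
        groups.setdefault(group, ([], []))
        groups[group][0].append(seq)
        groups[group][1].append(r.id)
    return [
        HaplotypeSample(group_id=g, sequences=s, ids=i) for g, (s, i) in groups.items()
    ]


def write_haplotype_list(path, samples: Sequence[HaplotypeSample]) -> None:
    """Arlequin-style haplotype list: group, haplotype string, count."""
    with open(path, "w") as fh:
        fh.write("group\thaplotype\tcount\n")
        for s in samples:
            haps: dict[str, int] = {}
            for seq in s.sequences:
                haps[seq] = haps.get(seq, 0) + 1
            for seq, count in sorted(haps.items()):
                fh.write(f"{s.group_id}\t{seq}\t{count}\n")


def read_haplotype_list(path) -> list[HaplotypeSample]:
    table = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
    for col in ("group", "haplotype", "count"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for group, sub in table.groupby("group", sort=False):
        seqs: list[str] = []
        for _, row in sub.iterrows():
            seqs.extend([row["haplotype"]] * int(row["count"]))
        out.append(HaplotypeSample(group_id=str(group), sequences=seqs))
    return out


# ---------------------------------------------------------------------------
# Tables and configuration
# ---------------------------------------------------------------------------


def write_stats_tsv(path, stats: np.ndarray, names: Sequence[str]) -> None:
    pd.DataFrame([dict(zip(names, stats))]).to_csv(path, sep="\t", index=False)


def write_reference_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_reference_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_config(path, config: dict) -> None:
    """Write a flat (one-level sections of scalars) TOML config."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        return json.dumps(str(v))

    with open(path, "w") as fh:
        scalars = {k: v for k, v in config.items() if not isinstance(v, dict)}
        for k, v in scalars.items():
            fh.write(f"{k} = {fmt(v)}\n")
        for section, sub in config.items():
            if isinstance(sub, dict):
                fh.write(f"\n[{section}]\n")
                for k, v in sub.items():
                    fh.write(f"{k} = {fmt(v)}\n")


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one CLI run."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        import danubesim

        return {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "versions": {
                "danubesim": danubesim.__version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
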