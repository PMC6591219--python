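"""Plain-text round-tripping for every format the pipeline touches.

All writers prepend ``#``-comment header lines carrying the tool version,
the config hash, and the seed of the run; all readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CountMatrix, PositionalCounts
from .survival import SurvivalSample


def _header(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    parts = [f"flylife v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return [" ".join(parts)]


def write_table(
    df: pd.DataFrame,
    path,
    sep: str = "\t",
    index: bool = True,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header(seed, config_hash):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# -- survival events ---------------------------------------------------------


def write_survival_csv(samples: list[SurvivalSample], path, **hdr) -> None:
    rows = []
    for sample in samples:
        for i, (t, e) in enumerate(zip(sample.times, sample.events)):
            rows.append(
                {
                    "id": f"{sample.label}:{i}",
                    "cohort": sample.label,
                    "sex": sample.sex,
                    "replicate": sample.replicate if sample.replicate is not None else "",
                    "time_days": t,
                    "event_flag": int(e),
                }
            )
    write_table(pd.DataFrame(rows), path, sep=",", index=False, **hdr)


def read_survival_csv(path) -> list[SurvivalSample]:
    df = pd.read_csv(path, comment="#")
    out = []
    for cohort, block in df.groupby("cohort", sort=True):
        rep = block["replicate"].iloc[0]
        out.append(
            SurvivalSample(
                times=block["time_days"].to_numpy(float),
                events=block["event_flag"].to_numpy(bool),
                label=str(cohort),
                sex=str(block["sex"].iloc[0]) if "sex" in block else "",
                replicate=int(rep) if pd.notna(rep) and str(rep) != "" else None,
            )
        )
    return out


# -- counts ------------------------------------------------------------------


def write_counts_tsv(cm: CountMatrix, path, **hdr) -> None:
    df = cm.values.copy()
    df.insert(0, "length", cm.gene_lengths)
    df.insert(1, "full_length", cm.full_lengths)
    write_table(df.rename_axis(index="gene_id"), path, **hdr)


def read_counts_tsv(path, sample_info: pd.DataFrame | None = None) -> CountMatrix:
    df = read_table(path)
    lengths = df.pop("length").astype(float)
    full = df.pop("full_length").astype(float) if "full_length" in df else None
    return CountMatrix(
        values=df, gene_lengths=lengths, full_lengths=full, sample_info=sample_info
    )


def write_positional_tsv(pc: PositionalCounts, path, **hdr) -> None:
    write_table(pc.to_frame(), path, index=False, **hdr)


def read_positional_tsv(
    path, bin_width: int, gene_of: dict[str, str], length_of: dict[str, int]
) -> PositionalCounts:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return PositionalCounts.from_frame(frame, bin_width, gene_of, length_of)


# -- sample sheets and activity ---------------------------------------------


def write_sample_sheet(info: pd.DataFrame, path, **hdr) -> None:
    write_table(info.rename_axis(index="sample"), path, sep=",", **hdr)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_activity_tsv(matrix: np.ndarray | pd.DataFrame, path, bin_width: float = 0.5, **hdr) -> None:
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(
            np.asarray(matrix),
            index=[f"fly_{i+1}" for i in range(len(matrix))],
            columns=[f"bin_{i}" for i in range(np.asarray(matrix).shape[1])],
        )
    write_table(matrix.rename_axis(index="fly"), path, **hdr)


def read_activity_tsv(path) -> pd.DataFrame:
    return read_table(path)


# -- gene sets ---------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line - name, description, then member gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "flylife") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
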