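"""Tabular input/output for the RIP-seq pipeline.

Everything the pipeline reads or writes is plain TSV (UTF-8, tab separated,
``.`` decimal, no quoting — the RSEM output convention):

* count matrices (transcripts x samples, first column = transcript id),
* RSEM ``*.isoforms.results`` files (``expected_count`` column),
* sample sheets (columns sample_id, condition, fraction, replicate),
* transcript -> gene-symbol annotation maps,
* GMT gene-set files,
* result tables, written with a ``#`` comment line recording tool version
  and a config hash so a run can be traced back to its settings.

Counts are kept as floats throughout: RSEM expected counts are fractional,
and integerization is the count model's concern, not the parser's.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CONDITIONS = ("CA", "FA")
FRACTIONS = ("input", "IP")


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleTable:
    """Assignment of libraries to the 2 (condition) x 2 (fraction) design.

    ``frame`` has one row per library with columns ``sample_id`` (unique),
    ``condition`` in {CA, FA}, ``fraction`` in {input, IP} and a positive
    integer ``replicate``, unique within its (condition, fraction) cell.
    A partial design (missing cells) is storable; :meth:`validate_design`
    enforces the full 2x2 layout required to run the pipeline.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition(s) {sorted(bad_cond)}; expected {CONDITIONS}")
        bad_frac = set(df["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(f"unknown fraction(s) {sorted(bad_frac)}; expected {FRACTIONS}")
        reps = df["replicate"]
        if not np.issubdtype(reps.dtype, np.integer) or (reps < 1).any():
            raise ValidationError("replicate must be a positive integer")
        if df.duplicated(subset=["condition", "fraction", "replicate"]).any():
            raise ValidationError("duplicate replicate number within a (condition, fraction) cell")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def select(self, condition: str | None = None, fraction: str | None = None) -> list[str]:
        """Sample ids matching the given condition and/or fraction."""
        df = self.frame
        mask = pd.Series(True, index=df.index)
        if condition is not None:
            mask &= df["condition"] == condition
        if fraction is not None:
            mask &= df["fraction"] == fraction
        return df.loc[mask, "sample_id"].tolist()

    def validate_design(self) -> None:
        """Require >=1 replicate in every (condition, fraction) cell."""
        for cond in CONDITIONS:
            for frac in FRACTIONS:
                if not self.select(cond, frac):
                    raise ConfigurationError(
                        f"design incomplete: no library for condition={cond}, fraction={frac}"
                    )

    def __len__(self) -> int:
        return len(self.frame)


def read_sample_sheet(path) -> SampleTable:
    """Read a sample sheet TSV (sample_id, condition, fraction, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    try:
        df["replicate"] = df["replicate"].astype(np.int64)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: bad or missing replicate column ({exc})") from exc
    return SampleTable(df.reset_index(drop=True))


def write_sample_sheet(samples: SampleTable, path) -> None:
    samples.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Transcripts x samples abundance table tied to a :class:`SampleTable`.

    ``values`` is a float DataFrame indexed by transcript id with one column
    per sample, in SampleTable order. Values are non-negative reals
    (fractional RSEM expected counts are legal).
    """

    values: pd.DataFrame
    samples: SampleTable

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].tolist()
            raise ValidationError(f"duplicate transcript_id(s): {dups[:5]}")
        if vals.columns.duplicated().any():
            raise ValidationError("duplicate sample columns in count matrix")
        want = self.samples.sample_ids
        missing = [s for s in want if s not in vals.columns]
        if missing:
            raise ConfigurationError(f"count matrix missing sample column(s): {missing}")
        # reorder (and drop extraneous columns) to match the sample sheet
        vals = vals[want].astype(float)
        neg = np.argwhere(vals.to_numpy() < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative count {vals.iat[r, c]} at transcript "
                f"{vals.index[r]!r}, sample {vals.columns[c]!r}"
            )
        self.values = vals

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Columns for the given samples, in the given order."""
        return self.values[list(sample_ids)]


def read_counts(path, samples: SampleTable) -> CountMatrix:
    """Read a transcripts x samples count TSV and validate it.

    The first column holds transcript ids; the header names samples. Every
    sample in ``samples`` must be present; columns are reordered to the
    sample-sheet order.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    for sid in samples.sample_ids:
        if sid not in df.columns:
            raise ConfigurationError(f"{path}: missing column for sample {sid!r}")
    return CountMatrix(df, samples)


def write_counts(counts: CountMatrix, path) -> None:
    """Write a count matrix as TSV (full float precision, exact round-trip)."""
    out = counts.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_rsem_results(paths: Mapping[str, str], samples: SampleTable) -> CountMatrix:
    """Assemble a CountMatrix from per-sample RSEM ``*.isoforms.results`` files.

    ``paths`` maps sample_id -> file path; every sample in ``samples`` needs a
    file. Transcripts present in only some files are zero-filled in the others
    (with a logged warning) so that downstream detected-in-one-condition-only
    rules still see them.
    """
    missing = [s for s in samples.sample_ids if s not in paths]
    if missing:
        raise ConfigurationError(f"no RSEM results file given for sample(s): {missing}")
    columns: dict[str, pd.Series] = {}
    order: list[str] = []
    seen: set[str] = set()
    for sid in samples.sample_ids:
        fpath = paths[sid]
        df = pd.read_csv(fpath, sep="\t")
        for col in ("transcript_id", "expected_count"):
            if col not in df.columns:
                raise FormatError(f"{fpath}: missing required column {col!r}")
        ser = pd.Series(
            df["expected_count"].to_numpy(float),
            index=df["transcript_id"].astype(str),
        )
        if ser.index.duplicated().any():
            raise ValidationError(f"{fpath}: duplicate transcript_id")
        columns[sid] = ser
        for tid in ser.index:
            if tid not in seen:
                seen.add(tid)
                order.append(tid)
    mat = pd.DataFrame(index=pd.Index(order, name="transcript_id"))
    for sid in samples.sample_ids:
        ser = columns[sid].reindex(order)
        n_missing = int(ser.isna().sum())
        if n_missing:
            logger.warning(
                "sample %s: %d transcript(s) absent from its RSEM file; zero-filled",
                sid,
                n_missing,
            )
        mat[sid] = ser.fillna(0.0)
    return CountMatrix(mat, samples)


# ---------------------------------------------------------------------------
# annotation map


def read_annotation(path) -> dict[str, str]:
    """Read a transcript_id -> gene_symbol TSV map (many-to-one allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("transcript_id", "gene_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["transcript_id"].duplicated().any():
        dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValidationError(f"{path}: duplicate transcript_id(s): {dups[:5]}")
    return dict(zip(df["transcript_id"], df["gene_symbol"]))


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets with unique names and non-empty member lists."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB member....

    Duplicate member symbols within a line are collapsed; a duplicate set
    name or a line with fewer than three fields is a format error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >=3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = GeneSet(name, desc, members)
    return GeneSetCollection(sets)


def write_gmt(genesets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# result tables


def config_hash(config_mapping: Mapping) -> str:
    """Short deterministic digest of a flat config mapping."""
    text = ";".join(f"{k}={config_mapping[k]}" for k in sorted(config_mapping))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_result_table(df: pd.DataFrame, path, *, config: Mapping | None = None) -> None:
    """Write a result table as TSV with a provenance comment line.

    Absent values are written as ``NA``.
    """
    from . import __version__

    header = f"# oxiseq {__version__}"
    if config is not None:
        header += f" config={config_hash(config)}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA")
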