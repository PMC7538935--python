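"""Synthetic 8-oxoG RIP-seq experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
2 condition (CA/FA) x 2 fraction (input/IP) design in biological
replicates; per-transcript input abundances drawn log-normally; IP counts
that mirror input abundance times a pulldown enrichment factor; planted
subsets of transcripts that are oxidation-enriched in the FA pulldown,
up-/down-regulated between the FA and CA inputs, or expressed only under
FA; negative-binomial counting noise (variance m + alpha*m^2); and
per-library depth variation. All randomness flows from a single root seed
through named spawned streams, so runs are reproducible and each stage's
draws are independent of the others.

Defaults mirror the emulated study design: 2 biological replicates per
cell, log-normal input abundances with median 200 counts, NB dispersion
0.05, 150 transcripts planted with a +4 log2-unit FA-specific pulldown
boost, 9 FA-only transcripts, and a planted DE subset at +/-5 log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CountMatrix, GeneSetCollection, SampleTable, read_gmt


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment; see module docstring."""

    n_transcripts: int = 5000
    replicates_per_cell: int = 2
    input_median: float = 200.0  # median of the log-normal abundance law
    input_log_sd: float = 1.0  # sd of ln(abundance)
    dispersion: float = 0.05  # NB dispersion alpha (variance m + alpha m^2)
    dispersion_cv: float = 0.0  # >0: per-transcript alpha ~ Gamma with this CV
    baseline_ip_log2: float = 0.0  # background pulldown enrichment, all transcripts
    n_enriched: int = 150
    delta_planted: float = 4.0  # extra FA-IP log2 enrichment for planted rows
    n_de_up: int = 50
    n_de_down: int = 50
    de_log2fc_planted: float = 5.0
    fa_only_count: int = 9
    library_size_log_sd: float = 0.15  # ln-scale sd of per-library depth factors
    library_size_factors: tuple[float, ...] | None = None  # explicit override
    fractional_counts: bool = False  # add sub-integer jitter (RSEM-style)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.replicates_per_cell < 1:
            raise ConfigurationError("n_transcripts and replicates_per_cell must be >= 1")
        planted = self.n_enriched + self.n_de_up + self.n_de_down + self.fa_only_count
        if min(self.n_enriched, self.n_de_up, self.n_de_down, self.fa_only_count) < 0:
            raise ConfigurationError("planted counts must be non-negative")
        if planted > self.n_transcripts:
            raise ConfigurationError(
                f"planted transcripts ({planted}) exceed n_transcripts ({self.n_transcripts})"
            )
        for name in ("input_median", "dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("input_log_sd", "delta_planted", "de_log2fc_planted", "dispersion_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        n_samples = 4 * self.replicates_per_cell
        if self.library_size_factors is not None and len(self.library_size_factors) != n_samples:
            raise ConfigurationError(
                f"library_size_factors needs {n_samples} entries, got "
                f"{len(self.library_size_factors)}"
            )

    def as_dict(self) -> dict:
        d = asdict(self)
        if d["library_size_factors"] is not None:
            d["library_size_factors"] = list(d["library_size_factors"])
        return d


def _design(replicates: int) -> SampleTable:
    rows = []
    for cond in ("CA", "FA"):
        for frac, tag in (("input", "IN"), ("IP", "IP")):
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cond}_{tag}_{rep}",
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    return SampleTable(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws with variance mean + alpha*mean^2; alpha -> 0 is Poisson."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    a = np.broadcast_to(alpha, mean.shape)[pos]
    m = mean[pos]
    tiny = a < 1e-8
    draws = np.empty(m.shape, dtype=np.int64)
    if tiny.any():
        draws[tiny] = rng.poisson(m[tiny])
    if (~tiny).any():
        r = 1.0 / a[~tiny]
        p = r / (r + m[~tiny])
        draws[~tiny] = rng.negative_binomial(r, p)
    out[pos] = draws
    return out


def simulate_experiment(config: SimConfig | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw one experiment; returns (counts, truth).

    ``truth`` is a per-transcript DataFrame with true_input_mean,
    true_ip_enrichment_ca/fa (log2), and the mutually exclusive planted
    flags is_enriched, is_up, is_down, is_fa_only.
    """
    config = config or SimConfig()
    root = np.random.SeedSequence(config.seed)
    s_abund, s_assign, s_lib, s_counts, s_jitter, s_disp = root.spawn(6)
    rng_abund = np.random.default_rng(s_abund)
    rng_assign = np.random.default_rng(s_assign)
    rng_lib = np.random.default_rng(s_lib)
    rng_counts = np.random.default_rng(s_counts)

    n = config.n_transcripts
    samples = _design(config.replicates_per_cell)
    n_samples = len(samples)
    tids = pd.Index([f"TX{i:06d}" for i in range(n)], name="transcript_id")

    abundance = rng_abund.lognormal(np.log(config.input_median), config.input_log_sd, n)

    # disjoint planted roles
    total_planted = config.n_enriched + config.n_de_up + config.n_de_down + config.fa_only_count
    picks = rng_assign.choice(n, size=total_planted, replace=False)
    cut1 = config.n_enriched
    cut2 = cut1 + config.n_de_up
    cut3 = cut2 + config.n_de_down
    is_enriched = np.zeros(n, bool)
    is_up = np.zeros(n, bool)
    is_down = np.zeros(n, bool)
    is_fa_only = np.zeros(n, bool)
    is_enriched[picks[:cut1]] = True
    is_up[picks[cut1:cut2]] = True
    is_down[picks[cut2:cut3]] = True
    is_fa_only[picks[cut3:]] = True

    if config.library_size_factors is not None:
        lib = np.asarray(config.library_size_factors, float)
    else:
        lib = rng_lib.lognormal(0.0, config.library_size_log_sd, n_samples)
        lib = lib / np.exp(np.mean(np.log(lib)))

    if config.dispersion_cv > 0:
        shape = 1.0 / config.dispersion_cv**2
        alpha = np.random.default_rng(s_disp).gamma(shape, config.dispersion / shape, n)
    else:
        alpha = np.full(n, config.dispersion)

    # condition-specific input means
    m_in_ca = abundance.copy()
    m_in_fa = abundance.copy()
    m_in_fa[is_up] *= 2.0**config.de_log2fc_planted
    m_in_fa[is_down] *= 2.0**-config.de_log2fc_planted
    m_in_ca[is_fa_only] = 0.0

    # pulldown enrichment on top of input abundance
    ip_ca_log2 = np.full(n, config.baseline_ip_log2)
    ip_fa_log2 = np.full(n, config.baseline_ip_log2)
    ip_fa_log2[is_enriched] += config.delta_planted
    m_ip_ca = m_in_ca * 2.0**ip_ca_log2
    m_ip_fa = m_in_fa * 2.0**ip_fa_log2

    mean_by_cell = {
        ("CA", "input"): m_in_ca,
        ("CA", "IP"): m_ip_ca,
        ("FA", "input"): m_in_fa,
        ("FA", "IP"): m_ip_fa,
    }
    mat = np.zeros((n, n_samples))
    for j, (_, row) in enumerate(samples.frame.iterrows()):
        mu = mean_by_cell[(row["condition"], row["fraction"])] * lib[j]
        mat[:, j] = _nb_draw(rng_counts, mu, alpha)
    if config.fractional_counts:
        jitter = np.random.default_rng(s_jitter).uniform(0.0, 0.5, mat.shape)
        mat = np.where(mat > 0, mat + jitter, mat)

    counts = CountMatrix(pd.DataFrame(mat, index=tids, columns=samples.sample_ids), samples)
    truth = pd.DataFrame(
        {
            "true_input_mean": abundance,
            "true_ip_enrichment_ca": ip_ca_log2,
            "true_ip_enrichment_fa": ip_fa_log2,
            "is_enriched": is_enriched,
            "is_up": is_up,
            "is_down": is_down,
            "is_fa_only": is_fa_only,
        },
        index=tids,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# packaged report-table fixture


def _parse_padj(text: str) -> float:
    """Printed adjusted p to a number; censored '<x' values -> their bound x."""
    text = str(text).strip()
    if text.startswith("<"):
        return float(text[1:])
    return float(text)


def load_report_table() -> pd.DataFrame:
    """The packaged 31-row report table (two pathway sections).

    Columns: pathway, gene_symbol, transcript_id, oxog_log2fc, de_log2fc,
    de_padj (numeric; censored "<0.0001" entries parsed to their printed
    bound), de_padj_printed (verbatim string). DE log2FC values are
    magnitudes as printed; their signs are not part of the fixture.
    """
    ref = resources.files("oxiseq.data") / "report_pathway_transcripts.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df["oxog_log2fc"] = df["oxog_log2fc"].astype(float)
    df["de_log2fc"] = df["de_log2fc"].astype(float)
    df["de_padj_printed"] = df["de_padj"]
    df["de_padj"] = df["de_padj_printed"].map(_parse_padj)
    return df


def load_report_genesets() -> GeneSetCollection:
    """The two packaged pathway gene sets (GMT)."""
    ref = resources.files("oxiseq.data") / "report_pathways.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)


def make_report_fixture(outdir=None) -> dict:
    """Assemble the packaged report-table fixture for pathway analyses.

    Returns a dict with:

    * ``table`` — the 31-row two-section report table,
    * ``genesets`` — the two pathway sets,
    * ``annotation`` — transcript_id -> gene_symbol map from the table,
    * ``results`` — a deduplicated per-transcript result frame (columns
      transcript_id, gene_symbol, enrichment, de_log2fc, de_padj) ready
      for :func:`oxiseq.pathways.tabulate_membership`; the one transcript
      listed in both sections keeps its first printed enrichment value.

    If ``outdir`` is given, the table (TSV) and gene sets (GMT) are also
    written there.
    """
    from .io import write_gmt

    table = load_report_table()
    genesets = load_report_genesets()
    annotation = dict(zip(table["transcript_id"], table["gene_symbol"]))
    results = (
        table.drop_duplicates(subset="transcript_id", keep="first")
        .rename(columns={"oxog_log2fc": "enrichment"})
        .loc[:, ["transcript_id", "gene_symbol", "enrichment", "de_log2fc", "de_padj"]]
        .reset_index(drop=True)
    )
    if outdir is not None:
        import os

        table_out = table.drop(columns=["de_padj"]).rename(
            columns={"de_padj_printed": "de_padj"}
        )
        table_out.to_csv(os.path.join(outdir, "report_pathway_transcripts.tsv"), sep="\t", index=False)
        write_gmt(genesets, os.path.join(outdir, "report_pathways.gmt"))
    return {"table": table, "genesets": genesets, "annotation": annotation, "results": results}
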