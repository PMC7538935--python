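"""Differential RNA-oxidation inference from 8-oxoG RIP-seq counts.

The design: two exposure conditions (CA = clean air, FA = formaldehyde),
each sequenced as an *input* fraction (the rRNA-depleted RNA pool, the
abundance reference) and an *IP* fraction (anti-8-oxoG antibody pulldown),
in biological replicates. Three pairwise contrasts are computed —

* CA_IP vs CA_IN  ->  ``ca_log2fc`` (background oxidation enrichment),
* FA_IP vs FA_IN  ->  ``fa_log2fc`` (oxidation enrichment under exposure),
* FA_IN vs CA_IN  ->  differential expression —

and no direct IP-vs-IP comparison, because pulldown counts are only
interpretable relative to their matched input. The differential-oxidation
statistic is the ratio of ratios

    delta_log2fc = fa_log2fc - ca_log2fc

(log2FC values of exactly 0.00 first raised to 0.01), gated by adjusted
significance of the IP/input enrichment in at least one condition and a
|delta| > 2 cutoff (a 4-fold ratio between the FA and CA fold changes).
Transcripts detected only in FA libraries are enriched by definition and
are added to the set. The DE branch calls up/down regulation at
p_adj < 0.05 and |log2FC| > 2, and the two branches intersect into the
headline "oxidized and downregulated" class.

The public surface follows the model/results idiom: build an
:class:`OxidationRIPSeq` from a :class:`~oxiseq.io.CountMatrix`, call
``fit()``, inspect the returned :class:`OxidationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix, GeneSetCollection, write_result_table
from .countmodel import (
    DEFAULT_DISPERSION_FLOOR,
    DEFAULT_PSEUDOCOUNT,
    NormalizationResult,
    nb_wald_contrast,
    size_factors,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the oxidation and DE branches.

    alpha_enrich
        adjusted-p gate for IP/input enrichment candidacy (default 0.05).
    delta_cutoff
        |delta_log2fc| cutoff; 2 log2 units = 4-fold ratio (default 2).
    alpha_de, de_fc_cutoff
        DE calls need p_adj < alpha_de and |log2FC| > de_fc_cutoff.
    zero_replacement
        value substituted for a log2FC of exactly 0.00 (default 0.01).
    fa_only_detection
        "all" (strict, default): FA-only requires count > 0 in *every* FA
        library; "any": in at least one. CA must be 0 everywhere either way.
    drop_all_zero
        drop transcripts with zero counts in every library before analysis.
    """

    alpha_enrich: float = 0.05
    delta_cutoff: float = 2.0
    alpha_de: float = 0.05
    de_fc_cutoff: float = 2.0
    zero_replacement: float = 0.01
    fa_only_detection: str = "all"
    drop_all_zero: bool = True
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    dispersion_floor: float = DEFAULT_DISPERSION_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_enrich", "alpha_de"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        for name in ("delta_cutoff", "de_fc_cutoff", "zero_replacement", "pseudocount"):
            v = getattr(self, name)
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive; got {v}")
        if self.fa_only_detection not in ("all", "any"):
            raise ConfigurationError(
                f"fa_only_detection must be 'all' or 'any'; got {self.fa_only_detection!r}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def zero_replace(log2fc, zero_replacement: float = 0.01):
    """Raise log2FC values of exactly 0.00 to the replacement value.

    Signed zeros are normalized first (``-0.0`` counts as zero); values
    merely *near* zero are left untouched. Accepts scalars or arrays.
    """
    arr = np.asarray(log2fc, float) + 0.0  # +0.0 folds -0.0 into +0.0
    out = np.where(arr == 0.0, zero_replacement, arr)
    if np.isscalar(log2fc) or np.ndim(log2fc) == 0:
        return float(out)
    return out


def ip_input_contrast(
    counts: CountMatrix,
    condition: str,
    config: PipelineConfig | None = None,
    norm: NormalizationResult | None = None,
) -> pd.DataFrame:
    """IP-vs-input NB Wald contrast for one condition.

    Positive log2fc means enriched in the pulldown. Size factors are
    computed on the four libraries of this contrast (each pairwise
    comparison is normalized on its own, as when the comparisons are run
    as separate two-group analyses).
    """
    config = config or PipelineConfig()
    inputs = counts.samples.select(condition, "input")
    ips = counts.samples.select(condition, "IP")
    if not inputs or not ips:
        raise ConfigurationError(
            f"condition {condition!r} lacks an input or IP library "
            f"(inputs={inputs}, IPs={ips})"
        )
    return nb_wald_contrast(
        counts,
        group_a=inputs,
        group_b=ips,
        norm=norm,
        pseudocount=config.pseudocount,
        dispersion_floor=config.dispersion_floor,
    )


def detect_fa_only(counts: CountMatrix, config: PipelineConfig | None = None) -> set[str]:
    """Transcripts detected in the FA libraries but in no CA library.

    Detection in FA follows ``config.fa_only_detection`` ("all" libraries,
    or "any"); absence from CA always means a count of exactly 0 in every
    CA library (input and IP alike).
    """
    config = config or PipelineConfig()
    fa_cols = counts.samples.select("FA")
    ca_cols = counts.samples.select("CA")
    fa = counts.subset(fa_cols).to_numpy() > 0
    ca_absent = (counts.subset(ca_cols).to_numpy() == 0).all(axis=1)
    fa_detected = fa.all(axis=1) if config.fa_only_detection == "all" else fa.any(axis=1)
    mask = fa_detected & ca_absent
    return set(counts.transcript_ids[mask])


def delta_enrichment(
    fa: pd.DataFrame,
    ca: pd.DataFrame,
    fa_only_ids: Iterable[str] = (),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Combine the per-condition contrasts into the delta-log2FC table.

    Columns: fa_log2fc, fa_padj, ca_log2fc, ca_padj, delta_log2fc,
    fa_only, candidate, enriched, depleted.

    candidate  = adjusted enrichment p < alpha in at least one condition;
    delta      = zero_replace(fa_log2fc) - zero_replace(ca_log2fc);
    enriched   = (candidate and delta > cutoff) or fa_only;
    depleted   = candidate and delta < -cutoff (the symmetric tail,
    reported for completeness).
    """
    config = config or PipelineConfig()
    if len(fa.index.intersection(ca.index)) == 0:
        raise ValidationError("FA and CA contrasts share no transcripts")
    idx = fa.index.union(ca.index, sort=False)
    fa = fa.reindex(idx)
    ca = ca.reindex(idx)
    zr = config.zero_replacement
    fa_l2 = fa["log2fc"].fillna(0.0).to_numpy()
    ca_l2 = ca["log2fc"].fillna(0.0).to_numpy()
    delta = zero_replace(fa_l2, zr) - zero_replace(ca_l2, zr)
    fa_padj = fa["p_adj"].to_numpy()
    ca_padj = ca["p_adj"].to_numpy()
    with np.errstate(invalid="ignore"):
        candidate = (fa_padj < config.alpha_enrich) | (ca_padj < config.alpha_enrich)
    candidate = np.where(np.isnan(fa_padj) & np.isnan(ca_padj), False, candidate)
    fa_only = idx.isin(set(fa_only_ids))
    enriched = (candidate & (delta > config.delta_cutoff)) | fa_only
    depleted = candidate & (delta < -config.delta_cutoff)
    return pd.DataFrame(
        {
            "fa_log2fc": fa_l2,
            "fa_padj": fa_padj,
            "ca_log2fc": ca_l2,
            "ca_padj": ca_padj,
            "delta_log2fc": delta,
            "fa_only": fa_only,
            "candidate": candidate.astype(bool),
            "enriched": enriched.astype(bool),
            "depleted": depleted.astype(bool),
        },
        index=idx.rename("transcript_id"),
    )


def differential_expression(
    counts: CountMatrix, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """FA-input vs CA-input contrast with up/down/unchanged status.

    Positive de_log2fc means higher abundance under formaldehyde. A call
    requires p_adj < alpha_de *and* |log2FC| > de_fc_cutoff; everything
    else (including untestable rows) is "unchanged".
    """
    config = config or PipelineConfig()
    ca_in = counts.samples.select("CA", "input")
    fa_in = counts.samples.select("FA", "input")
    if not ca_in or not fa_in:
        raise ConfigurationError("both conditions need input libraries for DE")
    res = nb_wald_contrast(
        counts,
        group_a=ca_in,
        group_b=fa_in,
        pseudocount=config.pseudocount,
        dispersion_floor=config.dispersion_floor,
    )
    l2 = res["log2fc"].to_numpy()
    padj = res["p_adj"].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = padj < config.alpha_de
    sig = np.where(np.isnan(padj), False, sig)
    status = np.where(
        sig & (l2 > config.de_fc_cutoff),
        "upregulated",
        np.where(sig & (l2 < -config.de_fc_cutoff), "downregulated", "unchanged"),
    )
    out = res.rename(
        columns={"log2fc": "de_log2fc", "se": "de_se", "p": "de_p", "p_adj": "de_padj"}
    )
    out["status"] = status
    return out


def intersect_oxidation_regulation(delta: pd.DataFrame, reg: pd.DataFrame) -> pd.DataFrame:
    """Fill the oxidation_class column by crossing the two branches.

    oxidized_down   enriched and downregulated;
    oxidized_other  enriched, not downregulated;
    not_oxidized_de not enriched but differentially expressed;
    background      everything else.
    """
    if set(delta.index) != set(reg.index):
        raise ValidationError("oxidation and regulation tables cover different transcripts")
    reg = reg.loc[delta.index].copy()
    enriched = delta["enriched"].to_numpy()
    status = reg["status"].to_numpy()
    de_called = status != "unchanged"
    cls = np.where(
        enriched & (status == "downregulated"),
        "oxidized_down",
        np.where(enriched, "oxidized_other", np.where(de_called, "not_oxidized_de", "background")),
    )
    reg["oxidation_class"] = cls
    return reg


def _min_positive(values: pd.DataFrame) -> float:
    arr = values.to_numpy(float)
    pos = arr[arr > 0]
    return float(pos.min()) if pos.size else float("nan")


def qc_summary(
    counts: CountMatrix,
    delta: pd.DataFrame,
    reg: pd.DataFrame,
    norms: Mapping[str, NormalizationResult] | None = None,
) -> pd.DataFrame:
    """Sanity metrics for a finished run as a (metric, value) table.

    Includes the minimum positive raw count among called transcripts in
    each branch — the check that calls are not driven by near-zero counts
    — along with library sizes, size factors and call tallies.
    """
    rows: list[tuple[str, float]] = []
    rows.append(("n_transcripts", float(counts.shape[0])))
    for sid in counts.samples.sample_ids:
        rows.append((f"library_size:{sid}", float(counts.values[sid].sum())))
    if norms:
        for label, norm in norms.items():
            for sid, f in norm.size_factors.items():
                rows.append((f"size_factor:{label}:{sid}", float(f)))
    rows.append(("n_candidates", float(delta["candidate"].sum())))
    rows.append(("n_enriched", float(delta["enriched"].sum())))
    rows.append(("n_fa_only", float(delta["fa_only"].sum())))
    rows.append(("n_depleted", float(delta["depleted"].sum())))
    status = reg["status"]
    rows.append(("n_upregulated", float((status == "upregulated").sum())))
    rows.append(("n_downregulated", float((status == "downregulated").sum())))
    if "oxidation_class" in reg:
        rows.append(
            ("n_oxidized_down", float((reg["oxidation_class"] == "oxidized_down").sum()))
        )
    enriched_ids = delta.index[delta["enriched"]]
    de_ids = reg.index[status != "unchanged"]
    input_cols = counts.samples.select(fraction="input")
    rows.append(
        (
            "min_positive_count_oxidation",
            _min_positive(counts.values.loc[counts.transcript_ids.isin(enriched_ids)]),
        )
    )
    rows.append(
        (
            "min_positive_count_de",
            _min_positive(counts.subset(input_cols).loc[counts.transcript_ids.isin(de_ids)]),
        )
    )
    return pd.DataFrame(rows, columns=["metric", "value"]).set_index("metric")


# ---------------------------------------------------------------------------
# model / results objects


class OxidationRIPSeq:
    """Differential-oxidation model for one RIP-seq experiment.

    Parameters
    ----------
    counts
        transcripts x samples CountMatrix over the full 2x2 design.
    config
        thresholds; defaults reproduce the standard gates
        (p_adj < 0.05 in >=1 condition, |delta| > 2, DE at p_adj < 0.05
        and |log2FC| > 2).
    annotation
        optional transcript_id -> gene symbol mapping used when writing
        reports and tabulating pathways.

    Examples
    --------
    >>> model = OxidationRIPSeq(counts)          # doctest: +SKIP
    >>> res = model.fit()                        # doctest: +SKIP
    >>> print(res.summary())                     # doctest: +SKIP
    """

    def __init__(
        self,
        counts: CountMatrix,
        config: PipelineConfig | None = None,
        annotation: Mapping[str, str] | None = None,
    ) -> None:
        counts.samples.validate_design()
        self.counts = counts
        self.config = config or PipelineConfig()
        self.annotation = dict(annotation) if annotation else {}

    @classmethod
    def from_files(
        cls,
        counts_path,
        samples_path,
        annotation_path=None,
        config: PipelineConfig | None = None,
    ) -> "OxidationRIPSeq":
        from .io import read_annotation, read_counts, read_sample_sheet

        samples = read_sample_sheet(samples_path)
        counts = read_counts(counts_path, samples)
        annotation = read_annotation(annotation_path) if annotation_path else None
        return cls(counts, config=config, annotation=annotation)

    def fit(self) -> "OxidationResults":
        cfg = self.config
        counts = self.counts
        if cfg.drop_all_zero:
            keep = (counts.values.to_numpy() > 0).any(axis=1)
            if not keep.all():
                counts = CountMatrix(counts.values.loc[keep], counts.samples)

        fa_only = detect_fa_only(counts, cfg)
        contrasts: dict[str, pd.DataFrame] = {}
        norms: dict[str, NormalizationResult] = {}
        for cond in ("CA", "FA"):
            cols = counts.samples.select(cond)
            norm = size_factors(counts.subset(cols))
            norms[cond] = norm
            contrasts[cond] = ip_input_contrast(counts, cond, cfg, norm=norm)
        delta = delta_enrichment(contrasts["FA"], contrasts["CA"], fa_only, cfg)
        reg = differential_expression(counts, cfg)
        reg = intersect_oxidation_regulation(delta, reg)
        contrasts["DE"] = reg
        norms["DE"] = size_factors(counts.subset(counts.samples.select(fraction="input")))
        qc = qc_summary(counts, delta, reg, norms)
        return OxidationResults(self, counts, delta, reg, contrasts, norms, qc)


class OxidationResults:
    """Fitted tables, diagnostics and reporting for one experiment."""

    def __init__(self, model, counts, enrichment, regulation, contrasts, norms, qc):
        self.model = model
        self.config: PipelineConfig = model.config
        self.counts: CountMatrix = counts
        self.enrichment: pd.DataFrame = enrichment
        self.regulation: pd.DataFrame = regulation
        self.contrasts: dict[str, pd.DataFrame] = contrasts
        self.norms: dict[str, NormalizationResult] = norms
        self.qc: pd.DataFrame = qc

    # -- views ------------------------------------------------------------

    @property
    def enriched_ids(self) -> pd.Index:
        return self.enrichment.index[self.enrichment["enriched"]]

    def symbol_for(self, transcript_id: str) -> str:
        return self.model.annotation.get(transcript_id, "")

    def results_frame(self) -> pd.DataFrame:
        """Per-transcript merged view of both branches (+ gene symbols)."""
        ann = self.model.annotation
        out = self.enrichment.copy()
        out.insert(0, "gene_symbol", [ann.get(t, "") for t in out.index])
        for col in ("de_log2fc", "de_padj", "status", "oxidation_class"):
            out[col] = self.regulation[col]
        return out

    def summary(self) -> str:
        """Human-readable run summary."""
        qc = self.qc["value"]
        cfg = self.config
        n = int(qc["n_transcripts"])
        lines = [
            "Differential RNA-oxidation analysis (8-oxoG RIP-seq)",
            "=" * 56,
            f"transcripts analysed          {n}",
            f"libraries                     {len(self.counts.samples)}",
            f"enrichment gate               p_adj < {cfg.alpha_enrich} in >=1 condition",
            f"delta cutoff                  |delta_log2fc| > {cfg.delta_cutoff}"
            f"  (ratio > {2 ** cfg.delta_cutoff:g})",
            f"DE gates                      p_adj < {cfg.alpha_de}, |log2FC| > {cfg.de_fc_cutoff}",
            "-" * 56,
            f"candidates (p_adj gate)       {int(qc['n_candidates'])}",
            f"oxidation-enriched            {int(qc['n_enriched'])}"
            f"  (FA-only: {int(qc['n_fa_only'])})",
            f"oxidation-depleted            {int(qc['n_depleted'])}",
            f"upregulated                   {int(qc['n_upregulated'])}",
            f"downregulated                 {int(qc['n_downregulated'])}",
            f"oxidized & downregulated      {int(qc['n_oxidized_down'])}",
            f"min positive count, oxidation {qc['min_positive_count_oxidation']:.4g}",
            f"min positive count, DE        {qc['min_positive_count_de']:.4g}",
        ]
        return "\n".join(lines)

    # -- pathway reporting -------------------------------------------------

    def pathway_membership(
        self, genesets: GeneSetCollection, alpha_de: float | None = None
    ) -> pd.DataFrame:
        from .pathways import tabulate_membership

        frame = self.results_frame()
        sel = frame.loc[frame["enriched"]].reset_index()
        sel = sel.rename(columns={"delta_log2fc": "enrichment"})
        return tabulate_membership(
            sel[["transcript_id", "gene_symbol", "enrichment", "de_log2fc", "de_padj"]],
            genesets,
            alpha_de=alpha_de if alpha_de is not None else self.config.alpha_de,
        )

    def pathway_ora(
        self, genesets: GeneSetCollection, universe: set[str] | None = None
    ) -> pd.DataFrame:
        from .pathways import hypergeometric_ora

        ann = self.model.annotation
        if universe is None:
            universe = {ann[t] for t in self.enrichment.index if t in ann}
        hits = {ann[t] for t in self.enriched_ids if t in ann}
        return hypergeometric_ora(hits, genesets, universe)

    # -- export ------------------------------------------------------------

    def to_tsv(self, outdir) -> dict[str, str]:
        """Write the standard result tables; returns {name: path}."""
        import os

        cfg = self.config.as_dict()
        frame = self.results_frame()
        paths = {}
        enr_cols = [
            "gene_symbol",
            "fa_log2fc",
            "fa_padj",
            "ca_log2fc",
            "ca_padj",
            "delta_log2fc",
            "fa_only",
            "candidate",
            "enriched",
            "depleted",
        ]
        de_cols = ["gene_symbol", "de_log2fc", "de_padj", "status", "oxidation_class"]
        for name, table in [
            ("oxidation_enrichment.tsv", frame[enr_cols]),
            ("differential_expression.tsv", frame[de_cols]),
            ("qc_summary.tsv", self.qc),
        ]:
            path = os.path.join(outdir, name)
            write_result_table(table, path, config=cfg)
            paths[name] = path
        return paths
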