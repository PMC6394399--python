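"""Haplotype panels, query sequences, and a synthetic mosaic generator.

A reference panel is an H x n matrix of small integer allele codes, one row
per haplotype and one column per biallelic (or multiallelic) site.  Panels
can be read from a trivial text format (one haplotype per line, digit codes,
no separators) or from the phased GT fields of a VCF.  The synthetic
generator produces panels with exactly the structure the Li & Stephens
copying model assumes: a small set of founder haplotypes, with every other
row (and the query) built as an imperfect mosaic of founder segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "QueryHaplotype",
    "QueryGenotype",
    "read_panel_text",
    "write_panel_text",
    "read_panel_vcf",
    "generate_mosaic_panel",
    "generate_mosaic_genotype",
]


class PanelFormatError(ValueError):
    """Raised for malformed panel input (ragged lines, bad characters, ...)."""


@dataclass
class HaplotypePanel:
    """An H x n matrix of allele codes representing a reference cohort."""

    alleles: np.ndarray
    alphabet_size: int = 2
    site_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise PanelFormatError("panel must be a 2-D matrix of allele codes")
        if self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise PanelFormatError("panel needs at least one haplotype and one site")
        if self.alphabet_size < 2:
            raise PanelFormatError("alphabet_size must be at least 2")
        if self.alleles.min() < 0 or self.alleles.max() >= self.alphabet_size:
            raise PanelFormatError(
                f"allele codes must lie in [0, {self.alphabet_size})"
            )
        if self.site_ids is not None and len(self.site_ids) != self.alleles.shape[1]:
            raise PanelFormatError("site_ids length must equal the number of sites")

    @property
    def H(self) -> int:
        return self.alleles.shape[0]

    @property
    def n(self) -> int:
        return self.alleles.shape[1]


@dataclass
class QueryHaplotype:
    """A single haplotype to be explained as a mosaic of panel rows."""

    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 1 or self.alleles.size < 1:
            raise PanelFormatError("query must be a nonempty 1-D allele vector")
        if self.alleles.min() < 0:
            raise PanelFormatError("query alleles must be nonnegative")

    @property
    def n(self) -> int:
        return self.alleles.size


@dataclass
class QueryGenotype:
    """An unphased diploid genotype sequence, values in {0, 1, 2}."""

    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 1 or self.genotypes.size < 1:
            raise PanelFormatError("genotypes must be a nonempty 1-D vector")
        if self.genotypes.min() < 0 or self.genotypes.max() > 2:
            raise PanelFormatError("genotype values must be 0, 1 or 2")

    @property
    def n(self) -> int:
        return self.genotypes.size


def read_panel_text(stream: IO[str] | Iterable[str]) -> HaplotypePanel:
    """Parse a plain-text panel: one haplotype per line, digit allele codes.

    The alphabet size is 1 + the largest observed code, with a minimum of 2.
    Ragged or non-digit lines raise :class:`PanelFormatError`.
    """
    rows: list[list[int]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        if not line.isdigit():
            raise PanelFormatError(
                f"line {lineno}: panel lines must contain only digit allele codes"
            )
        rows.append([int(c) for c in line])
    if not rows:
        raise PanelFormatError("no haplotype rows found")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise PanelFormatError("ragged panel: all lines must have equal length")
    alleles = np.array(rows, dtype=np.int64)
    alphabet = max(2, int(alleles.max()) + 1)
    return HaplotypePanel(alleles=alleles, alphabet_size=alphabet)


def write_panel_text(panel: HaplotypePanel, stream: IO[str]) -> None:
    """Inverse of :func:`read_panel_text` (round-trips any valid panel)."""
    for row in panel.alleles:
        stream.write("".join(str(int(a)) for a in row) + "\n")


def read_panel_vcf(
    path: str,
    region: Optional[tuple] = None,
    require_phased: bool = True,
) -> tuple[HaplotypePanel, list[str]]:
    """Read phased genotypes from a VCF into a binary haplotype panel.

    Each diploid sample contributes two panel rows (GT order preserved);
    columns follow record order.  Only biallelic records are used; others
    are skipped and counted in a log message.  ``region`` is an optional
    ``(chrom, start, end)`` triple filtering by 1-based position.

    Unphased GT fields raise unless ``require_phased=False``; missing GT
    values always raise (no imputation is attempted).
    """
    import pysam

    columns: list[list[int]] = []
    site_ids: list[str] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf.fetch() if region is None else vf.fetch(*region):
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped += 1
                continue
            col: list[int] = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    raise PanelFormatError(
                        f"missing GT at {rec.chrom}:{rec.pos}; imputation not supported"
                    )
                if require_phased and len(gt) > 1 and not sample.phased:
                    raise PanelFormatError(
                        f"unphased GT at {rec.chrom}:{rec.pos}; "
                        "pass require_phased=False to accept"
                    )
                col.extend(int(a) for a in gt)
            columns.append(col)
            site_ids.append(f"{rec.chrom}:{rec.pos}")
    if skipped:
        logger.info("skipped %d non-biallelic VCF records", skipped)
    if not columns:
        raise PanelFormatError("no usable biallelic records in VCF")
    alleles = np.array(columns, dtype=np.int64).T
    panel = HaplotypePanel(alleles=alleles, alphabet_size=2, site_ids=list(site_ids))
    return panel, site_ids


def _mosaic_rows(
    founders: np.ndarray,
    n_rows: int,
    switch_prob: float,
    flip_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rows copied as founder mosaics with per-site switch/flip noise."""
    n_founders, n = founders.shape
    choices = rng.integers(0, n_founders, size=(n_rows, n))
    switch = rng.random(size=(n_rows, n)) < switch_prob
    switch[:, 0] = True
    # index of the most recent switch point at each site, per row
    last = np.maximum.accumulate(
        np.where(switch, np.arange(n)[None, :], -1), axis=1
    )
    founder_at = np.take_along_axis(choices, last, axis=1)
    rows = founders[founder_at, np.arange(n)[None, :]]
    if flip_prob > 0:
        flips = rng.random(size=rows.shape) < flip_prob
        rows = np.where(flips, 1 - rows, rows)
    return rows


def generate_mosaic_panel(
    H: int,
    n: int,
    n_founders: int,
    switch_prob: float,
    flip_prob: float,
    seed: int,
) -> tuple[HaplotypePanel, QueryHaplotype]:
    """Generate a binary panel and query with Li & Stephens mosaic structure.

    The first ``n_founders`` rows are i.i.d. Bernoulli(0.5) founders; every
    remaining row and the query switch to a uniformly chosen founder with
    per-site probability ``switch_prob`` and flip each allele with per-site
    probability ``flip_prob``.  Deterministic given ``seed``.
    """
    if not (H >= n_founders >= 1):
        raise ValueError("need H >= n_founders >= 1")
    if n < 1:
        raise ValueError("need n >= 1")
    for p in (switch_prob, flip_prob):
        if not (0.0 <= p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 2, size=(n_founders, n))
    extra = _mosaic_rows(founders, H - n_founders, switch_prob, flip_prob, rng)
    alleles = np.vstack([founders, extra]) if H > n_founders else founders
    query = _mosaic_rows(founders, 1, switch_prob, flip_prob, rng)[0]
    return (
        HaplotypePanel(alleles=alleles, alphabet_size=2),
        QueryHaplotype(alleles=query),
    )


def generate_mosaic_genotype(
    H: int,
    n: int,
    n_founders: int,
    switch_prob: float,
    flip_prob: float,
    seed: int,
) -> tuple[HaplotypePanel, QueryGenotype]:
    """Like :func:`generate_mosaic_panel`, but the query is the site-wise sum
    of two independent founder mosaics — a diploid genotype sequence."""
    panel, _ = generate_mosaic_panel(H, n, n_founders, switch_prob, flip_prob, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    founders = panel.alleles[:n_founders]
    pair = _mosaic_rows(founders, 2, switch_prob, flip_prob, rng)
    return panel, QueryGenotype(genotypes=pair[0] + pair[1])
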