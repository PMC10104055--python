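"""Per-gene feature tensors: the linear F×10 block and the spatial column.

The linear block follows the ExPecto reduction: the ±20 kb window around the
TSS is scored in 200-bp bins and collapsed, per feature, into 10 positional
summaries — {upstream, downstream} × five exponential decay rates — where a
bin at |d| bins from the TSS contributes weight exp(−rate·|d|) to its side.
Upstream/downstream are oriented by gene strand.

The spatial column is the extension this package exists for: contact-map
pixels anchored at the TSS bin, reaching outside the ±20 kb linear scope,
with (balanced) count ≥ 0.5, name distal regions whose predicted signal is
summed per feature into one extra column, giving an F×11 tensor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import ContactMatrix, Gene

__all__ = [
    "DEFAULT_DECAY_RATES",
    "LinearTensor",
    "SpatialColumn",
    "GeneTensor",
    "DistalRegion",
    "build_linear_tensor",
    "select_spatial_contacts",
    "build_spatial_column",
    "assemble_tensor",
    "build_all_tensors",
    "strip_spatial",
]

logger = logging.getLogger(__name__)

# per 200-bp bin, matching the released ExPecto positional transformation
DEFAULT_DECAY_RATES = (0.01, 0.02, 0.05, 0.1, 0.2)


@dataclass
class LinearTensor:
    values: np.ndarray  # F × 10
    gene_id: str
    build_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 10:
            raise ValueError(f"linear tensor must be F×10, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.gene_id}: non-finite linear tensor")


@dataclass
class SpatialColumn:
    values: np.ndarray  # (F,)
    n_regions: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.n_regions < 0:
            raise ValueError("n_regions must be >= 0")


@dataclass
class GeneTensor:
    """F × C tensor, C = 11 when the spatial column is present (last column)."""

    values: np.ndarray
    spatial: bool
    gene_id: str

    def __post_init__(self) -> None:
        expected = 11 if self.spatial else 10
        if self.values.shape[1] != expected:
            raise ValueError(
                f"{self.gene_id}: spatial={self.spatial} requires {expected} columns, "
                f"got {self.values.shape[1]}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DistalRegion:
    """Genomic interval of a contact-partner bin, with its contact count."""

    chrom: str
    start: int
    end: int
    count: float


def build_linear_tensor(
    gene: Gene,
    predictor,
    window_bp: int = 20000,
    bin_bp: int = 200,
    decay_rates=DEFAULT_DECAY_RATES,
) -> LinearTensor:
    """Build the F×10 positional-summary block around the TSS.

    The 2·window_bp/bin_bp bins tile [TSS − window_bp, TSS + window_bp); the
    two bins adjacent to the TSS sit at distance 0 on their side. Bins beyond
    the chromosome ends contribute zero signal (zero-padding).
    Columns: upstream at rates r1..r5, then downstream at rates r1..r5.
    """
    if window_bp <= 0 or bin_bp <= 0:
        raise ValueError("window_bp and bin_bp must be positive")
    if window_bp % bin_bp:
        raise ValueError(f"bin_bp {bin_bp} must divide window_bp {window_bp}")
    rates = np.asarray(decay_rates, dtype=float)
    if len(rates) != 5 or np.any(rates <= 0):
        raise ValueError("decay_rates must be 5 positive reals")

    half = window_bp // bin_bp
    F = predictor.n_features
    chrom_len = predictor.chrom_length(gene.chrom)

    # F × (2·half) matrix of per-bin signal, zero outside the chromosome
    signal = np.zeros((F, 2 * half))
    for k in range(2 * half):
        s = gene.tss - window_bp + k * bin_bp
        e = s + bin_bp
        cs, ce = max(s, 0), min(e, chrom_len)
        if ce <= cs:
            continue
        # zero-padding: out-of-chromosome stretch contributes 0 to the bin mean
        signal[:, k] = predictor.predict_window(gene.chrom, cs, ce) * ((ce - cs) / bin_bp)

    left = signal[:, :half][:, ::-1]  # distance 0..half-1 walking away from TSS
    right = signal[:, half:]
    if gene.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left

    d = np.arange(half)
    weights = np.exp(-rates[:, None] * d[None, :])  # 5 × half
    cols = np.concatenate([upstream @ weights.T, downstream @ weights.T], axis=1)
    return LinearTensor(
        cols,
        gene.gene_id,
        build_params={
            "window_bp": window_bp,
            "bin_bp": bin_bp,
            "decay_rates": list(map(float, rates)),
        },
    )


def select_spatial_contacts(
    gene: Gene,
    contacts: ContactMatrix,
    linear_scope_bp: int = 20000,
    min_count: float = 0.5,
) -> list[DistalRegion]:
    """Select distal contact-partner bins for one gene.

    A pixel qualifies when (i) one anchor is the bin containing the TSS,
    (ii) the partner bin's interval does not overlap
    [TSS − linear_scope_bp, TSS + linear_scope_bp), and (iii) its stored
    count is at least ``min_count``. The TSS bin itself is never returned;
    results are sorted by genomic position.
    """
    if not contacts.has_chrom(gene.chrom):
        raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in contact matrix")
    res = contacts.resolution
    tss_bin = gene.tss // res
    scope_lo = gene.tss - linear_scope_bp
    scope_hi = gene.tss + linear_scope_bp

    regions = []
    for i, j, c in contacts.pixels(gene.chrom):
        if i == tss_bin and j == tss_bin:
            continue
        if i == tss_bin:
            partner = j
        elif j == tss_bin:
            partner = i
        else:
            continue
        if c < min_count:
            continue
        start, end = contacts.bin_interval(gene.chrom, partner)
        if start < scope_hi and end > scope_lo:  # overlaps the linear scope
            continue
        regions.append(DistalRegion(gene.chrom, start, end, c))
    regions.sort(key=lambda r: r.start)
    return regions


def build_spatial_column(
    gene: Gene,
    regions: list[DistalRegion],
    predictor,
    window_bp: int = 200,
) -> SpatialColumn:
    """Sum predicted signal over all distal regions, tiled at ``window_bp``.

    Summing (not averaging) keeps the tensor a fixed F×1 regardless of how
    many regions a gene has, while letting the column scale with the total
    contacted territory. No regions → a zero column.
    """
    F = predictor.n_features
    total = np.zeros(F)
    for region in regions:
        tiles = predictor.predict_tiled(region.chrom, region.start, region.end, window_bp)
        total += tiles.sum(axis=0)
    return SpatialColumn(total, n_regions=len(regions), gene_id=gene.gene_id)


def assemble_tensor(linear: LinearTensor, spatial: SpatialColumn | None = None) -> GeneTensor:
    """Concatenate the linear block and (optionally) the spatial column."""
    if spatial is None:
        return GeneTensor(linear.values.copy(), spatial=False, gene_id=linear.gene_id)
    if spatial.gene_id != linear.gene_id:
        raise ValueError(f"gene_id mismatch: {linear.gene_id!r} vs {spatial.gene_id!r}")
    if spatial.values.shape[0] != linear.values.shape[0]:
        raise ValueError(
            f"{linear.gene_id}: F mismatch (linear {linear.values.shape[0]}, "
            f"spatial {spatial.values.shape[0]})"
        )
    values = np.concatenate([linear.values, spatial.values[:, None]], axis=1)
    return GeneTensor(values, spatial=True, gene_id=linear.gene_id)


def build_all_tensors(
    genes: list[Gene],
    predictor,
    contacts: ContactMatrix | None = None,
    window_bp: int = 20000,
    bin_bp: int = 200,
    decay_rates=DEFAULT_DECAY_RATES,
    linear_scope_bp: int = 20000,
    min_count: float = 0.5,
    spatial_window_bp: int = 200,
) -> dict[str, GeneTensor]:
    """Build one tensor per gene: F×11 when ``contacts`` is given, else F×10.

    A gene whose chromosome is absent from the contact matrix gets a zero
    spatial column (logged), so one missing ChIA-PET chromosome does not
    abort a whole run.
    """
    if not genes:
        raise ValueError("no genes given")
    out: dict[str, GeneTensor] = {}
    for n, gene in enumerate(genes):
        linear = build_linear_tensor(gene, predictor, window_bp, bin_bp, decay_rates)
        if contacts is None:
            out[gene.gene_id] = assemble_tensor(linear)
        else:
            if contacts.has_chrom(gene.chrom):
                regions = select_spatial_contacts(gene, contacts, linear_scope_bp, min_count)
            else:
                logger.warning(
                    "%s: chromosome %s absent from contact matrix; zero spatial column",
                    gene.gene_id,
                    gene.chrom,
                )
                regions = []
            spatial = build_spatial_column(gene, regions, predictor, spatial_window_bp)
            out[gene.gene_id] = assemble_tensor(linear, spatial)
        if (n + 1) % 500 == 0:
            logger.info("built %d/%d tensors", n + 1, len(genes))
    return out


def strip_spatial(tensor: GeneTensor) -> GeneTensor:
    """Baseline view of a spatial tensor: the first 10 columns, bit-identical."""
    if not tensor.spatial:
        return tensor
    return GeneTensor(tensor.values[:, :10].copy(), spatial=False, gene_id=tensor.gene_id)
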