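"""Read-level barcode quantification for pooled deletion-library competitions.

Turns raw amplicon reads (or pre-made count tables) into filtered, normalized
mutant-abundance tables. The counting rules are deliberately strict: a read
contributes to a gene's count only when the barcode immediately downstream of
the upstream flanking sequence matches a catalog barcode *perfectly* and at
full length. Barcodes shared by more than one gene are discarded up front,
strains too rare in the starting pool are dropped, and a pseudocount keeps
every relative abundance strictly positive.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VESSELS = ("shake_flask", "bioreactor")
_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CatalogFormatError(ValueError):
    """Malformed barcode catalog (bad row, non-ACGT barcode, mixed lengths)."""


class FastqFormatError(ValueError):
    """Truncated or structurally invalid FASTQ record."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample.

    ``time_h`` is elapsed fermentation time in hours for the condition the
    sample belongs to (seed-train samples carry their own clock).
    """

    sample_id: str
    condition: str
    vessel: str = "bioreactor"
    time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.vessel not in VESSELS:
            raise ValueError(
                f"vessel must be one of {VESSELS}, got {self.vessel!r}"
            )
        if self.time_h < 0:
            raise ValueError(f"time_h must be non-negative, got {self.time_h}")


@dataclass
class BarcodeCatalog:
    """Unambiguous barcode -> gene map.

    ``entries`` holds (barcode, gene) pairs after exact duplicates are
    collapsed; any barcode observed with more than one distinct gene is moved
    to ``discarded_ambiguous`` and never counted.
    """

    entries: list[tuple[str, str]]
    discarded_ambiguous: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for barcode, gene in self.entries:
            if not set(barcode) <= _DNA:
                raise CatalogFormatError(f"non-ACGT barcode {barcode!r}")
            if barcode in seen and seen[barcode] != gene:
                raise CatalogFormatError(
                    f"barcode {barcode!r} maps to multiple genes; "
                    "ambiguous barcodes belong in discarded_ambiguous"
                )
            seen[barcode] = gene
        lengths = {len(b) for b, _ in self.entries}
        if len(lengths) > 1:
            raise CatalogFormatError(f"mixed barcode lengths {sorted(lengths)}")
        overlap = set(seen) & set(self.discarded_ambiguous)
        if overlap:
            raise CatalogFormatError(
                f"barcodes both retained and discarded: {sorted(overlap)[:5]}"
            )

    @property
    def barcode_length(self) -> int:
        if not self.entries:
            raise ValueError("empty catalog has no barcode length")
        return len(self.entries[0][0])

    @property
    def genes(self) -> list[str]:
        """Retained gene identifiers in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for _, gene in self.entries:
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
        return out

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self.entries)

    def barcode_for(self, gene: str) -> str:
        """First retained barcode of ``gene`` (genes may carry several tags)."""
        for barcode, g in self.entries:
            if g == gene:
                return barcode
        raise KeyError(gene)


def load_catalog(path: str | Path) -> BarcodeCatalog:
    """Parse a barcode catalog TSV (header columns ``barcode``, ``gene``).

    Exact duplicate rows collapse to one entry; a barcode shared by several
    distinct genes is discarded as ambiguous. Malformed rows and mixed barcode
    lengths raise :class:`CatalogFormatError` naming the offending line.
    """
    path = Path(path)
    pairs: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            bc_col = header.index("barcode")
            gene_col = header.index("gene")
        except ValueError:
            raise CatalogFormatError(
                f"{path}: header must contain 'barcode' and 'gene' columns, "
                f"got {header}"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise CatalogFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            barcode, gene = fields[bc_col], fields[gene_col]
            if not barcode or not set(barcode) <= _DNA:
                raise CatalogFormatError(
                    f"{path}:{lineno}: barcode {barcode!r} has non-ACGT characters"
                )
            pairs.setdefault(barcode, set()).add(gene)
    lengths = {len(b) for b in pairs}
    if len(lengths) > 1:
        raise CatalogFormatError(
            f"{path}: mixed barcode lengths {sorted(lengths)}"
        )
    entries = [(b, next(iter(g))) for b, g in pairs.items() if len(g) == 1]
    discarded = sorted(b for b, g in pairs.items() if len(g) > 1)
    if discarded:
        logger.info(
            "discarded %d ambiguous barcode(s) shared by multiple genes",
            len(discarded),
        )
    return BarcodeCatalog(entries=entries, discarded_ambiguous=discarded)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_barcode(
    read: str, upstream_flank: str, barcode_length: int
) -> str | None:
    """Barcode immediately following the first exact flank occurrence.

    Returns ``None`` when the flank is absent or fewer than ``barcode_length``
    bases remain past it. Quality scores play no role: the downstream
    perfect-match rule already discards errored reads.
    """
    if not upstream_flank:
        raise ValueError("upstream_flank must be non-empty")
    pos = read.find(upstream_flank)
    if pos < 0:
        return None
    start = pos + len(upstream_flank)
    barcode = read[start : start + barcode_length]
    if len(barcode) < barcode_length:
        return None
    return barcode


def _iter_fastq(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (record_index, sequence) from FASTQ or FASTQ.gz."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                _, seq, _ = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: invalid FASTQ record {index}: {exc}"
                ) from exc
            yield index, seq.upper()
            index += 1


@dataclass
class CountSummary:
    total_reads: int = 0
    matched: int = 0
    unmatched: int = 0
    ambiguous_discarded: int = 0


class CountTable:
    """Samples x genes integer read counts with per-sample metadata.

    ``counts`` is a pandas DataFrame indexed by sample_id with one column per
    gene; ``meta`` is indexed identically with columns ``condition``,
    ``vessel`` and ``time_h``.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame) -> None:
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample_id in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate gene in count table")
        if not counts.index.equals(meta.index):
            raise ValueError("counts and meta must share the same sample index")
        missing = {"condition", "vessel", "time_h"} - set(meta.columns)
        if missing:
            raise ValueError(f"meta missing columns {sorted(missing)}")
        values = counts.to_numpy()
        if values.size and (
            not np.issubdtype(values.dtype, np.integer) or (values < 0).any()
        ):
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64, copy=False) if values.size else counts
        self.meta = meta

    # -- construction -------------------------------------------------
    @classmethod
    def from_samples(
        cls, rows: Sequence[tuple[SampleMeta, dict[str, int] | pd.Series]]
    ) -> "CountTable":
        metas = [m for m, _ in rows]
        counts = pd.DataFrame(
            [pd.Series(c, dtype=np.int64) for _, c in rows],
            index=[m.sample_id for m in metas],
        ).fillna(0).astype(np.int64)
        meta = pd.DataFrame(
            {
                "condition": [m.condition for m in metas],
                "vessel": [m.vessel for m in metas],
                "time_h": [m.time_h for m in metas],
            },
            index=[m.sample_id for m in metas],
        )
        return cls(counts, meta)

    # -- accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def sample_metas(self) -> list[SampleMeta]:
        return [
            SampleMeta(sid, row["condition"], row["vessel"], float(row["time_h"]))
            for sid, row in self.meta.iterrows()
        ]

    def samples_for(self, condition: str) -> pd.DataFrame:
        """Metadata of the condition's samples ordered by time."""
        sub = self.meta[self.meta["condition"] == condition]
        return sub.sort_values("time_h", kind="stable")

    def concat(self, other: "CountTable") -> "CountTable":
        counts = pd.concat([self.counts, other.counts]).fillna(0).astype(np.int64)
        meta = pd.concat([self.meta, other.meta])
        return CountTable(counts, meta)

    # -- I/O ----------------------------------------------------------
    def to_tsv(
        self,
        counts_path: str | Path,
        samples_path: str | Path,
        header_comment: str | None = None,
    ) -> None:
        _write_tsv(self.counts.T.rename_axis("gene"), counts_path, header_comment)
        _write_tsv(
            self.meta.rename_axis("sample_id"), samples_path, header_comment
        )

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, samples_path: str | Path
    ) -> "CountTable":
        counts = pd.read_csv(
            counts_path, sep="\t", comment="#", index_col="gene"
        ).T.astype(np.int64)
        counts.index.name = None
        meta = pd.read_csv(
            samples_path, sep="\t", comment="#", index_col="sample_id"
        )
        meta.index.name = None
        meta = meta.loc[counts.index]
        return cls(counts, meta)


def _write_tsv(
    frame: pd.DataFrame, path: str | Path, header_comment: str | None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t")


class AbundanceTable:
    """Pseudocounted relative abundances; every row sums to one."""

    def __init__(
        self, abundance: pd.DataFrame, meta: pd.DataFrame, pseudocount: int
    ) -> None:
        values = abundance.to_numpy(dtype=float)
        if values.size:
            if (values < 0).any():
                raise ValueError("abundances must be non-negative")
            rowsums = values.sum(axis=1)
            if not np.allclose(rowsums, 1.0, atol=1e-9):
                raise ValueError("abundance rows must sum to 1 within 1e-9")
            if pseudocount > 0 and (values <= 0).any():
                raise ValueError(
                    "pseudocounted abundances must be strictly positive"
                )
        self.abundance = abundance
        self.meta = meta
        self.pseudocount = pseudocount

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def genes(self) -> list[str]:
        return list(self.abundance.columns)

    def to_tsv(
        self,
        abundance_path: str | Path,
        samples_path: str | Path,
        header_comment: str | None = None,
    ) -> None:
        _write_tsv(
            self.abundance.T.rename_axis("gene"), abundance_path, header_comment
        )
        _write_tsv(self.meta.rename_axis("sample_id"), samples_path, header_comment)


def count_reads(
    reads: str | Path | Iterable[str],
    catalog: BarcodeCatalog,
    meta: SampleMeta,
    upstream_flank: str,
    barcode_length: int | None = None,
    search_revcomp: bool = False,
    summary: CountSummary | None = None,
) -> CountTable:
    """Count perfect barcode matches in one sample's reads.

    A read contributes only when its extracted barcode matches a retained
    catalog barcode exactly and at full length; reads without the flank, with
    any mismatch, or carrying a discarded ambiguous barcode are dropped.
    ``reads`` may be a FASTQ(.gz) path or an iterable of sequence strings.
    """
    if barcode_length is None:
        barcode_length = catalog.barcode_length
    lookup = catalog.mapping
    discarded = set(catalog.discarded_ambiguous)
    counts: dict[str, int] = dict.fromkeys(catalog.genes, 0)
    stats = summary if summary is not None else CountSummary()

    if isinstance(reads, (str, Path)):
        source: Iterable[tuple[int, str]] = _iter_fastq(reads)
    else:
        source = enumerate(reads)

    for _, seq in source:
        stats.total_reads += 1
        barcode = extract_barcode(seq, upstream_flank, barcode_length)
        if barcode is None and search_revcomp:
            barcode = extract_barcode(
                reverse_complement(seq), upstream_flank, barcode_length
            )
        if barcode is not None and barcode in lookup:
            counts[lookup[barcode]] += 1
            stats.matched += 1
        elif barcode is not None and barcode in discarded:
            stats.ambiguous_discarded += 1
        else:
            stats.unmatched += 1

    logger.info(
        "sample %s: %d reads, %d matched, %d unmatched, %d ambiguous-discarded",
        meta.sample_id,
        stats.total_reads,
        stats.matched,
        stats.unmatched,
        stats.ambiguous_discarded,
    )
    return CountTable.from_samples([(meta, counts)])


def filter_t0(
    table: CountTable, t0_sample: str, threshold: int = 10
) -> CountTable:
    """Restrict to genes with at least ``threshold`` counts in the t0 sample.

    Strains too rare in the starting pool are statistically uninformative and
    are dropped from every sample; the input table is left unmodified. The
    operation is idempotent.
    """
    if t0_sample not in table.counts.index:
        raise KeyError(f"t0 sample {t0_sample!r} not in table")
    keep = table.counts.loc[t0_sample] >= threshold
    return CountTable(table.counts.loc[:, keep].copy(), table.meta.copy())


def normalize(table: CountTable, pseudocount: int = 10) -> AbundanceTable:
    """Pseudocount and normalize counts into relative abundances.

    Every count is increased by ``pseudocount`` and divided by the sample's
    adjusted total, so rows sum to exactly 1 and entries are strictly
    positive — a proper composition for downstream dissimilarity measures.
    """
    if table.n_genes == 0:
        raise ValueError("nothing to normalize: table has no genes")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    adjusted = table.counts.astype(float) + float(pseudocount)
    abundance = adjusted.div(adjusted.sum(axis=1), axis=0)
    return AbundanceTable(abundance, table.meta.copy(), pseudocount)
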