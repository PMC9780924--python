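"""Minimal GFF3 gene-feature reader/writer.

Only ``gene`` features with ``ID=`` attributes are consumed; coordinates are
converted between GFF's 1-based inclusive convention and the package's
0-based half-open convention at this boundary and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from famforge.evolution import GeneLocus


class GffParseError(ValueError):
    pass


@dataclass
class FeatureTable:
    loci: dict[str, GeneLocus] = field(default_factory=dict)

    def add(self, locus: GeneLocus) -> None:
        if locus.gene_id in self.loci:
            raise ValueError(f"duplicate gene id {locus.gene_id!r}")
        self.loci[locus.gene_id] = locus

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, gene_id: str) -> GeneLocus:
        return self.loci[gene_id]

    def __iter__(self):
        return iter(self.loci.values())


def read_gff(path: str | Path) -> FeatureTable:
    """Parse gene features; 1-based inclusive -> 0-based half-open."""
    table = FeatureTable()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError:
                raise GffParseError(
                    f"{path}:{lineno}: non-numeric coordinate {start_s!r}/{end_s!r}"
                ) from None
            if end_1 < start_1:
                raise GffParseError(f"{path}:{lineno}: end < start")
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:].strip()
                    break
            if not gene_id:
                raise GffParseError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                table.add(GeneLocus(gene_id, chrom, start_1 - 1, end_1, strand))
            except ValueError as exc:
                raise GffParseError(f"{path}:{lineno}: {exc}") from None
    return table


def write_gff(table: FeatureTable, path: str | Path, source: str = "famforge") -> None:
    """Write gene features, converting back to 1-based inclusive exactly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in table:
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        source,
                        "gene",
                        str(locus.start + 1),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.gene_id}",
                    ]
                )
                + "\n"
            )
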