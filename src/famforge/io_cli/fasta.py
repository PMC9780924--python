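"""FASTA reading and writing with strict alphabet validation.

A deliberately small parser: the package needs line-numbered parse errors,
duplicate-id detection and a fixed 60-column writer so that identical inputs
always produce byte-identical files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")
_ALPHABETS = {"protein": PROTEIN_ALPHABET, "dna": DNA_ALPHABET}

WRAP = 60


class FastaParseError(ValueError):
    pass


@dataclass
class SequenceStore:
    """Ordered id -> sequence mapping with an alphabet tag."""

    alphabet: str
    records: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"alphabet must be 'protein' or 'dna', got {self.alphabet!r}")

    def add(self, seq_id: str, sequence: str, description: str = "") -> None:
        if seq_id in self.records:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        if not sequence:
            raise ValueError(f"empty sequence for id {seq_id!r}")
        bad = set(sequence) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"sequence {seq_id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)}"
            )
        self.records[seq_id] = sequence
        if description:
            self.descriptions[seq_id] = description

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]

    def __iter__(self):
        return iter(self.records)

    def items(self):
        return self.records.items()


def read_fasta(path: str | Path, alphabet: str) -> SequenceStore:
    """Parse a FASTA file; uppercases, strips one trailing ``*``, validates.

    Errors (duplicate id, empty record, illegal character) are raised as
    :class:`FastaParseError` carrying the offending line number.
    """
    store = SequenceStore(alphabet)
    path = Path(path)
    header: str | None = None
    header_line = 0
    description = ""
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        try:
            store.add(header, seq, description)
        except ValueError as exc:
            raise FastaParseError(f"{path}:{header_line}: {exc}") from None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split(maxsplit=1)
                if not fields:
                    raise FastaParseError(f"{path}:{lineno}: header with no id")
                header, description = fields[0], fields[1] if len(fields) > 1 else ""
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.strip())
    flush()
    return store


def write_fasta(store: SequenceStore, path: str | Path) -> None:
    """Write records in insertion order, wrapped to 60 columns."""
    with open(path, "w") as fh:
        for seq_id, seq in store.items():
            desc = store.descriptions.get(seq_id, "")
            fh.write(f">{seq_id} {desc}\n" if desc else f">{seq_id}\n")
            for k in range(0, len(seq), WRAP):
                fh.write(seq[k : k + WRAP] + "\n")


def write_fasta_dict(
    records: dict[str, str], path: str | Path, alphabet: str = "protein"
) -> None:
    store = SequenceStore(alphabet)
    for seq_id, seq in records.items():
        store.add(seq_id, seq)
    write_fasta(store, path)
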