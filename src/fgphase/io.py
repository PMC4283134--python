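"""FASTA input/output for FG-domain records.

Record descriptions may carry ``key=value`` tokens, e.g.::

    >ScNup100 organism=S.cerevisiae glebs=109-167

``glebs`` is a 1-based inclusive residue interval excluded from
composition and charge/hydropathy statistics.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import FGDomainRecord


def _parse_interval(text: str) -> tuple[int, int]:
    lo, _, hi = text.partition("-")
    return int(lo), int(hi)


def parse_description_tokens(description: str) -> dict[str, str]:
    tokens = {}
    for word in description.split()[1:]:  # first word is the id
        if "=" in word:
            key, _, value = word.partition("=")
            tokens[key.lower()] = value
    return tokens


def read_fasta(
    path: str | Path,
    glebs_map: dict[str, tuple[int, int]] | None = None,
    source: str = "user",
) -> list[FGDomainRecord]:
    """Read a multi-record FASTA into FGDomainRecords.

    GLEBS intervals are taken from ``glebs_map`` (id -> (start, end))
    when given, otherwise from a ``glebs=start-end`` header token.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = parse_description_tokens(rec.description)
        glebs = None
        if glebs_map and rec.id in glebs_map:
            glebs = glebs_map[rec.id]
        elif "glebs" in tokens:
            glebs = _parse_interval(tokens["glebs"])
        records.append(FGDomainRecord(
            id=rec.id,
            residues=str(rec.seq),
            organism=tokens.get("organism", ""),
            glebs_interval=glebs,
            source=source,
        ))
    return records


def write_fasta(records: list[FGDomainRecord], path: str | Path) -> None:
    """Write records to FASTA, encoding GLEBS/organism as header tokens."""
    seq_records = []
    for rec in records:
        tokens = []
        if rec.organism:
            tokens.append(f"organism={rec.organism}")
        if rec.glebs_interval:
            tokens.append(f"glebs={rec.glebs_interval[0]}-"
                          f"{rec.glebs_interval[1]}")
        seq_records.append(SeqRecord(
            Seq(rec.residues), id=rec.id, description=" ".join(tokens)))
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_glebs_map(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a two-column TSV/whitespace file: record id, start-end."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rec_id, interval = line.split()[:2]
        mapping[rec_id] = _parse_interval(interval)
    return mapping
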