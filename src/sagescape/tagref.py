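"""Virtual tag reference: transcript -> expected tag, tag -> transcript set.

The tag of a transcript is the ``tag_len`` bases immediately 3' of the
3'-most anchor occurrence in its sense-strand sequence (3'-terminal
fragments are the ones retained by oligo-dT capture). Transcripts with no
anchor, too few bases downstream of the last anchor, or ambiguous bases in
the tag region are recorded as untaggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .layout import LibraryLayout

UNTAGGABLE = "untaggable"
_VALID = set("ACGT")


@dataclass
class TagReference:
    tag_index: dict[str, list[str]] = field(default_factory=dict)
    untaggable: list[str] = field(default_factory=list)
    tag_len: int = 19
    anchor: str = "CATG"

    @property
    def n_transcripts(self) -> int:
        return len(self.untaggable) + sum(len(v) for v in self.tag_index.values())

    def lookup(self, tag: str) -> list[str]:
        """Exact-match lookup; queries are normalized to uppercase."""
        tag = tag.upper()
        if len(tag) != self.tag_len:
            raise ValueError(f"query length {len(tag)} != tag_len {self.tag_len}")
        return list(self.tag_index.get(tag, []))

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as (tag, comma-joined ids); untaggable ids keyed by sentinel."""
        with open(path, "w") as fh:
            fh.write(f"#tag_len={self.tag_len}\tanchor={self.anchor}\n")
            for tag in sorted(self.tag_index):
                fh.write(f"{tag}\t{','.join(self.tag_index[tag])}\n")
            if self.untaggable:
                fh.write(f"{UNTAGGABLE}\t{','.join(self.untaggable)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagReference":
        tag_index: dict[str, list[str]] = {}
        untaggable: list[str] = []
        tag_len, anchor = 19, "CATG"
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    meta = dict(p.split("=") for p in line[1:].split("\t"))
                    tag_len = int(meta.get("tag_len", tag_len))
                    anchor = meta.get("anchor", anchor)
                    continue
                key, ids = line.split("\t")
                if key == UNTAGGABLE:
                    untaggable = ids.split(",")
                else:
                    tag_index[key] = ids.split(",")
        return cls(tag_index, untaggable, tag_len, anchor)


def extract_transcript_tag(seq: str, layout: LibraryLayout) -> str:
    """Tag of one sense-strand transcript sequence, or the untaggable sentinel."""
    seq = seq.upper()
    pos = seq.rfind(layout.anchor)
    if pos == -1:
        return UNTAGGABLE
    start = pos + layout.anchor_len
    tag = seq[start : start + layout.tag_len]
    if len(tag) < layout.tag_len or set(tag) - _VALID:
        return UNTAGGABLE
    return tag


def build_tag_reference(
    transcripts: str | Path | Iterable[tuple[str, str]],
    layout: LibraryLayout | None = None,
) -> TagReference:
    """Build the tag reference from a FASTA path or (id, sequence) pairs.

    Raises on an empty input or duplicate transcript ids. Transcripts
    sharing a tag are listed under one key in input order (the multi-map
    case that the quantification stage averages over).
    """
    layout = layout or LibraryLayout()
    if isinstance(transcripts, (str, Path)):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(transcripts), "fasta")]
    else:
        records = list(transcripts)
    if not records:
        raise ValueError("no transcript sequences provided")
    seen: set[str] = set()
    ref = TagReference(tag_len=layout.tag_len, anchor=layout.anchor)
    for tid, seq in records:
        if tid in seen:
            raise ValueError(f"duplicate transcript id: {tid}")
        seen.add(tid)
        tag = extract_transcript_tag(seq, layout)
        if tag == UNTAGGABLE:
            ref.untaggable.append(tid)
        else:
            ref.tag_index.setdefault(tag, []).append(tid)
    return ref
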