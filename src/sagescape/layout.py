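"""Library read/construct geometry.

A single-end read of a tag library is laid out as::

    barcode | degenerate bases | anchor (CATG) | tag | linker fill

The full amplified construct is ``5' linker + insert + 3' barcoded linker``,
where the insert is the span between the type III enzyme's recognition site
and its cut point on the shorter-cut strand (anchor + tag + two-base
overhang).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class LayoutError(ValueError):
    """Raised when a layout's geometry is internally inconsistent."""


@dataclass(frozen=True)
class LibraryLayout:
    """Sequence geometry of one tag-library read and its source construct.

    Defaults describe a 50 bp single-end read carrying a 6 nt sample
    barcode, two degenerate bases, the CATG anchor and a 19 bp tag, cut
    from a 119 bp amplified construct.
    """

    barcode_len: int = 6
    degenerate_len: int = 2
    anchor: str = "CATG"
    tag_len: int = 19
    linker5_len: int = 47
    linker3_len: int = 47  # includes the barcode
    read_len: int = 50
    ecop15i_cut_short: int = 25
    ecop15i_cut_long: int = 27

    def __post_init__(self) -> None:
        self.validate()

    @property
    def anchor_len(self) -> int:
        return len(self.anchor)

    @property
    def insert_len(self) -> int:
        """Recognition-site-to-cut span on the shorter-cut strand."""
        return self.anchor_len + self.tag_len + self.degenerate_len

    @property
    def construct_len(self) -> int:
        """Full amplified library construct length in bp."""
        return self.linker5_len + self.ecop15i_cut_short + self.linker3_len

    @property
    def tag_start(self) -> int:
        """0-based offset of the tag within a read."""
        return self.barcode_len + self.degenerate_len + self.anchor_len

    @property
    def min_read_len(self) -> int:
        return self.barcode_len + self.degenerate_len + self.anchor_len + self.tag_len

    def validate(self) -> None:
        if not self.anchor or set(self.anchor) - set("ACGT"):
            raise LayoutError(f"anchor must be a non-empty ACGT string, got {self.anchor!r}")
        if self.tag_len < 1:
            raise LayoutError("tag_len must be positive")
        if self.insert_len != self.ecop15i_cut_short:
            raise LayoutError(
                f"anchor+tag+degenerate span ({self.insert_len}) must equal the "
                f"short-strand cut distance ({self.ecop15i_cut_short})"
            )
        if self.ecop15i_cut_long != self.ecop15i_cut_short + 2:
            raise LayoutError("long-strand cut must exceed the short-strand cut by 2 nt")
        if self.read_len < self.min_read_len:
            raise LayoutError(
                f"read_len {self.read_len} shorter than barcode+degenerate+anchor+tag "
                f"({self.min_read_len})"
            )
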