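"""Stockholm alignment IO.

Stockholm is the native alignment format: sequences plus file-level
``#=GF`` tags (including the embedded Newick tree under ``NH``),
per-column ``#=GC`` tags and per-sequence-per-column ``#=GR`` tags, each
block terminated by ``//``.  Multi-block files are supported for batch
processing.  The writer emits a canonical unwrapped form, so
write(read(x)) is byte-stable; the reader accepts wrapped input by
concatenating repeated sequence/annotation lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .tree import PhyloTree, parse_newick, write_newick

__all__ = ["StockholmAlignment", "read_stockholm", "write_stockholm",
           "StockholmError"]


class StockholmError(ValueError):
    pass


@dataclass
class StockholmAlignment:
    """One alignment block: ordered rows plus GF/GC/GR annotations."""

    rows: Dict[str, str] = field(default_factory=dict)
    gf: List[Tuple[str, str]] = field(default_factory=list)
    gc: Dict[str, str] = field(default_factory=dict)
    gr: Dict[str, Dict[str, str]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def names(self) -> List[str]:
        return list(self.rows)

    def gf_values(self, tag: str) -> List[str]:
        return [v for t, v in self.gf if t == tag]

    def set_gf(self, tag: str, value: str) -> None:
        self.gf = [(t, v) for t, v in self.gf if t != tag]
        self.gf.append((tag, value))

    @property
    def tree(self) -> Optional[PhyloTree]:
        """Tree embedded under the ``#=GF NH`` tag (multi-line values are
        concatenated into one Newick string)."""
        parts = self.gf_values("NH")
        if not parts:
            return None
        return parse_newick("".join(parts))

    def embed_tree(self, tree: PhyloTree) -> None:
        self.set_gf("NH", write_newick(tree))

    def validate(self) -> None:
        L = self.n_columns
        for name, row in self.rows.items():
            if len(row) != L:
                raise StockholmError(
                    f"row {name!r} has length {len(row)}, expected {L}")
        for tag, s in self.gc.items():
            if len(s) != L:
                raise StockholmError(
                    f"#=GC {tag} has length {len(s)}, expected {L}")
        for name, tags in self.gr.items():
            for tag, s in tags.items():
                if len(s) != L:
                    raise StockholmError(
                        f"#=GR {name} {tag} has length {len(s)}, "
                        f"expected {L}")


def read_stockholm(source: Union[str, io.TextIOBase]) -> List[StockholmAlignment]:
    """Parse all alignment blocks from Stockholm text or a stream."""
    text = source.read() if hasattr(source, "read") else source
    blocks: List[StockholmAlignment] = []
    aln = StockholmAlignment()
    saw_content = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# STOCKHOLM"):
            continue
        if line.strip() == "//":
            if saw_content:
                aln.validate()
                blocks.append(aln)
            aln, saw_content = StockholmAlignment(), False
            continue
        if line.startswith("#=GF"):
            parts = line.split(None, 2)
            if len(parts) < 2:
                raise StockholmError(f"line {lineno}: malformed #=GF line")
            aln.gf.append((parts[1], parts[2] if len(parts) > 2 else ""))
            saw_content = True
        elif line.startswith("#=GC"):
            parts = line.split()
            if len(parts) != 3:
                raise StockholmError(f"line {lineno}: malformed #=GC line")
            aln.gc[parts[1]] = aln.gc.get(parts[1], "") + parts[2]
            saw_content = True
        elif line.startswith("#=GR"):
            parts = line.split()
            if len(parts) != 4:
                raise StockholmError(f"line {lineno}: malformed #=GR line")
            tags = aln.gr.setdefault(parts[1], {})
            tags[parts[2]] = tags.get(parts[2], "") + parts[3]
            saw_content = True
        elif line.startswith("#=GS") or line.startswith("#"):
            continue
        else:
            parts = line.split()
            if len(parts) != 2:
                raise StockholmError(
                    f"line {lineno}: malformed sequence line {line!r}")
            name, seq = parts
            aln.rows[name] = aln.rows.get(name, "") + seq
            saw_content = True
    if saw_content:
        aln.validate()
        blocks.append(aln)
    return blocks


def write_stockholm(alignments: Union[StockholmAlignment,
                                      Iterable[StockholmAlignment]],
                    stream: Optional[io.TextIOBase] = None) -> str:
    """Serialize alignment block(s) in canonical (unwrapped) form."""
    if isinstance(alignments, StockholmAlignment):
        alignments = [alignments]
    out = io.StringIO()
    for aln in alignments:
        aln.validate()
        out.write("# STOCKHOLM 1.0\n")
        for tag, value in aln.gf:
            out.write(f"#=GF {tag} {value}\n")
        width = max(
            [len(n) for n in aln.rows]
            + [len(f"#=GR {n} {t}") for n, ts in aln.gr.items() for t in ts]
            + [len(f"#=GC {t}") for t in aln.gc]
            + [0]) + 2
        for name, row in aln.rows.items():
            out.write(f"{name:<{width}}{row}\n")
            for tag, s in aln.gr.get(name, {}).items():
                key = f"#=GR {name} {tag}"
                out.write(f"{key:<{width}}{s}\n")
        for tag, s in aln.gc.items():
            key = f"#=GC {tag}"
            out.write(f"{key:<{width}}{s}\n")
        out.write("//\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
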