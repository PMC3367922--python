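"""Annotation track output: GFF features and WIG quantitative tracks.

Coordinates are 1-based inclusive *alignment columns* (annotations
describe the alignment, not any one ungapped sequence);
:func:`project_to_sequence` maps a feature onto one row's ungapped
coordinates when needed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

__all__ = ["GFFFeature", "WigTrack", "write_gff", "write_wig",
           "project_to_sequence"]


@dataclass
class GFFFeature:
    """One GFF line: 9 tab-delimited fields, GFF2 attribute syntax."""

    seqid: str
    source: str
    type: str
    start: int            # 1-based inclusive
    end: int              # inclusive
    score: Union[float, str, None] = None
    strand: str = "."
    frame: str = "."
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature coordinates {self.start}..{self.end}")

    def line(self) -> str:
        score = "." if self.score is None else (
            self.score if isinstance(self.score, str)
            else f"{self.score:.4g}")
        attrs = " ".join(f'{k} "{v}";' for k, v in self.attributes.items())
        return "\t".join([self.seqid, self.source, self.type,
                          str(self.start), str(self.end), str(score),
                          self.strand, self.frame, attrs or "."])


@dataclass
class WigTrack:
    """fixedStep track: one value per alignment column, 1-based."""

    name: str
    values: Sequence[float]
    chrom: str = "alignment"

    def lines(self) -> List[str]:
        out = [f'track type=wiggle_0 name="{self.name}"',
               f"fixedStep chrom={self.chrom} start=1 step=1"]
        out.extend(f"{v:.6g}" for v in self.values)
        return out


def write_gff(features: Iterable[GFFFeature],
              stream: Optional[io.TextIOBase] = None) -> str:
    text = "".join(f.line() + "\n" for f in features)
    if stream is not None:
        stream.write(text)
    return text


def write_wig(track: WigTrack,
              stream: Optional[io.TextIOBase] = None) -> str:
    text = "".join(l + "\n" for l in track.lines())
    if stream is not None:
        stream.write(text)
    return text


def project_to_sequence(feature: GFFFeature, row: str,
                        gap_chars: str = "-._") -> Optional[GFFFeature]:
    """Project an alignment-coordinate feature onto one ungapped row.

    Returns None when the feature covers no non-gap position of the row.
    """
    pos_map, p = [], 0
    for ch in row:
        if ch in gap_chars:
            pos_map.append(None)
        else:
            p += 1
            pos_map.append(p)
    covered = [pos_map[c] for c in range(feature.start - 1, feature.end)
               if pos_map[c] is not None]
    if not covered:
        return None
    return GFFFeature(feature.seqid, feature.source, feature.type,
                      covered[0], covered[-1], feature.score,
                      feature.strand, feature.frame,
                      dict(feature.attributes))
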