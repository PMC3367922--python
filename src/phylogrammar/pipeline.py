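"""End-to-end processing behind the command line.

Per alignment block the documented order is: parse the Stockholm file
and the grammar alphabet (macros may depend on both); expand grammar
macros; take the embedded tree or estimate one by neighbor-joining on
Jukes-Cantor-corrected distances; train parameters if requested;
annotate if requested; reconstruct ancestral sequences if requested.
The annotated alignment (with the tree embedded) goes to the output
stream; the trained grammar, GFF and WIG go to their own files when
flags direct them there.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .annotate import ParseAnnotation, annotate
from .grammar import Grammar, read_grammar, write_grammar
from .stockholm import StockholmAlignment, read_stockholm, write_stockholm
from .tracks import write_gff, write_wig
from .training import em_train
from .tree import PhyloTree, jc_distance_matrix, neighbor_joining

__all__ = ["PipelineOptions", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineOptions:
    train_out: Optional[Path] = None      # -t: train and write grammar here
    band: Optional[int] = None            # -l: maximum pairing distance
    ancestral: bool = False               # -ar: most probable ancestors
    ancestral_pp: bool = False            # -arpp: posterior probabilities
    gff_out: Optional[Path] = None        # -gff (default: standard output)
    wig_out: Optional[Path] = None        # -wig (default: standard output)
    annotate: bool = True
    max_iter: int = 30
    tol: float = 1e-4
    wig_nonterminal: Optional[str] = None
    param_aliases: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    alignments: List[StockholmAlignment]
    annotations: List[Optional[ParseAnnotation]]
    trees: List[PhyloTree]
    trained: Optional[Grammar] = None
    stockholm_text: str = ""
    gff_text: str = ""
    wig_text: str = ""


def _tree_for(aln: StockholmAlignment) -> PhyloTree:
    tree = aln.tree
    if tree is None:
        names = aln.names
        d = jc_distance_matrix([aln.rows[n] for n in names])
        tree = neighbor_joining(d, names)
    tree.auto_label()
    return tree


def run_pipeline(grammar_file: Union[str, Path], alignment_file:
                 Union[str, Path, io.TextIOBase],
                 options: Optional[PipelineOptions] = None,
                 stdout: Optional[io.TextIOBase] = None) -> PipelineResult:
    """Run the full processing order on every block of a Stockholm file."""
    opts = options or PipelineOptions()
    text = (alignment_file.read() if hasattr(alignment_file, "read")
            else Path(alignment_file).read_text())
    blocks = read_stockholm(text)
    if not blocks:
        raise ValueError("no alignment blocks in input")

    trees = [_tree_for(b) for b in blocks]
    grammars = []
    for b, t in zip(blocks, trees):
        grammars.append(read_grammar(Path(grammar_file), tree=t,
                                     n_columns=b.n_columns,
                                     param_aliases=opts.param_aliases))
    g = grammars[0]

    trained = None
    if opts.train_out is not None:
        result = em_train(g, blocks, trees, max_iter=opts.max_iter,
                          tol=opts.tol, band=opts.band)
        trained = result.grammar
        Path(opts.train_out).write_text(write_grammar(trained))
        g = trained

    annotations: List[Optional[ParseAnnotation]] = []
    out_blocks: List[StockholmAlignment] = []
    gff_parts: List[str] = []
    wig_parts: List[str] = []
    for i, (block, tree) in enumerate(zip(blocks, trees)):
        ga = grammars[i] if trained is None else trained
        out = StockholmAlignment(dict(block.rows), list(block.gf),
                                 dict(block.gc), {k: dict(v) for k, v
                                                  in block.gr.items()})
        out.embed_tree(tree)
        ann = None
        if opts.annotate:
            seqid = f"alignment{i + 1}" if len(blocks) > 1 else "alignment"
            ann = annotate(ga, block, tree, band=opts.band,
                           ancestral=opts.ancestral or opts.ancestral_pp,
                           wig_nonterminal=opts.wig_nonterminal,
                           seqid=seqid)
            out.gc[ga.gc_tag] = ann.gc_label
            for name, tags in ann.gr_class.items():
                out.gr.setdefault(name, {}).update(tags)
            if opts.ancestral or opts.ancestral_pp:
                for node_label, seq in ann.ancestral.items():
                    out.rows[node_label] = seq
                    if opts.ancestral_pp:
                        pp = "".join(str(min(9, int(p * 10)))
                                     for p in ann.ancestral_pp[node_label])
                        out.gr.setdefault(node_label, {})["PP"] = pp
            gff_parts.append(write_gff(ann.gff))
            wig_parts.append(write_wig(ann.wig))
        annotations.append(ann)
        out_blocks.append(out)

    stk_text = write_stockholm(out_blocks)
    gff_text = "".join(gff_parts)
    wig_text = "".join(wig_parts)

    stream = stdout if stdout is not None else sys.stdout
    stream.write(stk_text)
    if opts.annotate:
        if opts.gff_out is not None:
            Path(opts.gff_out).write_text(gff_text)
        if opts.wig_out is not None:
            Path(opts.wig_out).write_text(wig_text)
        if opts.gff_out is None and opts.wig_out is None and gff_text:
            # annotations go to standard output by default
            stream.write(gff_text)

    return PipelineResult(out_blocks, annotations, trees, trained,
                          stk_text, gff_text, wig_text)
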