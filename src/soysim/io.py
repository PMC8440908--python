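"""Plain-text exports: VCF for genotypes, TSV for the genetic map."""

from __future__ import annotations

import numpy as np

from .genome import GeneticMap, MarkerPanel, Population

__all__ = ["write_vcf", "write_map_table"]


def _bp_position(gmap: GeneticMap, chrom: int, pos_cm: float) -> int:
    # physical coordinates are proportional to map distance (bookkeeping only)
    frac = pos_cm / gmap.lengths_cm[chrom]
    return int(frac * (gmap.spans_bp[chrom] - 1)) + 1


def write_vcf(pop: Population, panel: MarkerPanel, path) -> None:
    """Phased GT export of the panel markers, one sample per individual."""
    gmap = pop.gmap
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=soysim\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={int(gmap.spans_bp[c])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{int(i)}" for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        h = pop.haplotypes
        for k, s in enumerate(panel.site_indices):
            c = int(gmap.site_chrom[s])
            bp = _bp_position(gmap, c, float(gmap.site_pos[s]))
            gts = "\t".join(f"{h[i, 0, s]}|{h[i, 1, s]}" for i in range(pop.n_individuals))
            fh.write(f"chr{c + 1}\t{bp}\tm{k}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_map_table(gmap: GeneticMap, path) -> None:
    """Three-column text table: chromosome, site index, position in cM."""
    off = gmap.chrom_offsets
    with open(path, "w") as fh:
        fh.write("chrom\tsite\tcM\n")
        for s in range(gmap.total_sites):
            c = int(gmap.site_chrom[s])
            fh.write(f"{c + 1}\t{s - off[c]}\t{gmap.site_pos[s]:.6f}\n")
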