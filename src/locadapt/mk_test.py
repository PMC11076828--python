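"""Per-gene McDonald-Kreitman tests from in-frame codon alignments.

Counts fixed nonsynonymous/synonymous differences against an outgroup CDS
(Dn, Ds) and nonsynonymous/synonymous polymorphisms within the ingroup
(Pn, Ps), applies a one-sided Fisher exact test in the direction of excess
nonsynonymous divergence, and Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

VALID_BASES = frozenset("ACGT")


@dataclass
class CodingGene:
    """An in-frame gene: ingroup haplotype CDSs plus one outgroup CDS."""

    gene_id: str
    ingroup_seqs: list[str]
    outgroup_seq: str

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.ingroup_seqs} | {len(self.outgroup_seq)}
        if len(lens) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        (length,) = lens
        if length % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {length} not divisible by 3")


@dataclass
class MKCounts:
    gene_id: str
    dn: float = 0.0
    ds: float = 0.0
    pn: float = 0.0
    ps: float = 0.0
    n_excluded_codons: int = 0
    p: float = 1.0
    q: float = 1.0

    @property
    def direction_positive(self) -> bool:
        """True when divergence is nonsynonymous-biased (Dn/Ds > Pn/Ps)."""
        return self.dn * self.ps > self.ds * self.pn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsyn, syn) step counts between codons, averaged over all orderings.

    Every ordering of the differing positions is weighted equally; paths pass
    through intermediate codons (stop codons included — no path exclusion).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    n_sum = s_sum = 0.0
    n_orders = 0
    for order in itertools.permutations(diffs):
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s_sum += 1
            else:
                n_sum += 1
            cur = nxt
        n_orders += 1
    return n_sum / n_orders, s_sum / n_orders


def count_mk(gene: CodingGene) -> MKCounts:
    """Fractional Dn/Ds/Pn/Ps for one gene.

    Per codon, positions where the ingroup segregates contribute polymorphism
    counts; positions where the ingroup is fixed and differs from the
    outgroup contribute divergence counts.  A position polymorphic in the
    ingroup is never counted as fixed, whatever the outgroup carries.
    Codons with gaps or ambiguous bases in any sequence are excluded and
    tallied.  Multi-difference codons are resolved by pathway averaging.
    """
    out = MKCounts(gene.gene_id)
    length = len(gene.outgroup_seq)
    for c0 in range(0, length, 3):
        in_codons = [s[c0:c0 + 3].upper() for s in gene.ingroup_seqs]
        out_codon = gene.outgroup_seq[c0:c0 + 3].upper()
        if any(set(c) - VALID_BASES for c in in_codons + [out_codon]):
            out.n_excluded_codons += 1
            continue
        # major ingroup codon = most common; ties broken alphabetically
        counts: dict[str, int] = {}
        for c in in_codons:
            counts[c] = counts.get(c, 0) + 1
        major = sorted(counts, key=lambda c: (-counts[c], c))[0]
        poly_pos = [i for i in range(3)
                    if len({c[i] for c in in_codons}) > 1]
        fixed_pos = [i for i in range(3)
                     if i not in poly_pos and major[i] != out_codon[i]]

        if fixed_pos:
            # path between the outgroup codon and the codon made of the
            # ingroup's fixed alleles, holding polymorphic positions at major
            target = "".join(major[i] if i in fixed_pos or i in poly_pos
                             else out_codon[i] for i in range(3))
            start = "".join(major[i] if i in poly_pos else out_codon[i]
                            for i in range(3))
            dn, ds = _pathway_counts(start, target)
            out.dn += dn
            out.ds += ds
        if poly_pos:
            # star from the major codon to each minor variant
            for minor in sorted(set(in_codons) - {major}):
                pn, ps = _pathway_counts(major, minor)
                out.pn += pn
                out.ps += ps
    return out


def round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


def mk_fisher(counts: MKCounts) -> float:
    """One-sided Fisher exact p for excess nonsynonymous divergence.

    The 2x2 table is [[Dn, Ds], [Pn, Ps]] with fractional pathway counts
    rounded half-up; genes with an empty divergence or polymorphism row get
    p = 1.
    """
    dn, ds = round_half_up(counts.dn), round_half_up(counts.ds)
    pn, ps = round_half_up(counts.pn), round_half_up(counts.ps)
    if min(dn, ds, pn, ps) < 0:
        raise ValueError("negative MK counts")
    if dn + ds == 0 or pn + ps == 0:
        return 1.0
    _, p = fisher_exact([[dn, ds], [pn, ps]], alternative="greater")
    return float(p)


def mk_g_test(counts: MKCounts, williams: bool = True) -> float:
    """Two-sided G test of independence on the MK table (optional statistic).

    Applies the Williams continuity correction by default; degenerate margins
    give p = 1.
    """
    t = np.array([[round_half_up(counts.dn), round_half_up(counts.ds)],
                  [round_half_up(counts.pn), round_half_up(counts.ps)]],
                 dtype=float)
    if t.sum() == 0 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        return 1.0
    n = t.sum()
    expect = np.outer(t.sum(1), t.sum(0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expect), 0.0)
    g = 2.0 * terms.sum()
    if williams:
        qcorr = 1.0 + ((n / t.sum(1)).sum() - 1) * ((n / t.sum(0)).sum() - 1) \
            / (6.0 * n)
        g /= qcorr
    return float(chi2.sf(g, df=1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mk_table(genes) -> pd.DataFrame:
    """Run counts + Fisher + BH over genes; one row per gene."""
    counts = [count_mk(g) for g in genes]
    for c in counts:
        c.p = mk_fisher(c)
    qs = bh_adjust([c.p for c in counts])
    for c, q in zip(counts, qs):
        c.q = float(q)
    return pd.DataFrame({
        "gene": [c.gene_id for c in counts],
        "Dn": [c.dn for c in counts], "Ds": [c.ds for c in counts],
        "Pn": [c.pn for c in counts], "Ps": [c.ps for c in counts],
        "p": [c.p for c in counts], "q": [c.q for c in counts],
        "direction": ["positive" if c.direction_positive else "none"
                      for c in counts],
        "excluded_codons": [c.n_excluded_codons for c in counts],
    })


def positive_selection_genes(table: pd.DataFrame, q_cutoff: float = 0.05,
                             ) -> list[str]:
    """Genes significant after BH and divergence-biased in direction."""
    sel = (table["q"] < q_cutoff) & (table["direction"] == "positive")
    return table.loc[sel, "gene"].tolist()


# ---------------------------------------------------------------------------
# FASTA alignment input


def read_gene_alignment(path: str | Path, outgroup_name: str = "outgroup",
                        ) -> CodingGene:
    """Read one per-gene FASTA: ingroup haplotype CDSs plus one outgroup CDS.

    The outgroup record is the one whose header contains ``outgroup_name``;
    the gene id is the file stem.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    out_keys = [k for k in seqs if outgroup_name in k]
    if len(out_keys) != 1:
        raise ValueError(f"{path}: expected exactly one outgroup record, "
                         f"found {len(out_keys)}")
    outgroup = seqs.pop(out_keys[0])
    return CodingGene(path.stem, list(seqs.values()), outgroup)


def read_gene_alignments(directory: str | Path,
                         outgroup_name: str = "outgroup") -> list[CodingGene]:
    files = sorted(Path(directory).glob("*.fasta")) \
        + sorted(Path(directory).glob("*.fa"))
    return [read_gene_alignment(f, outgroup_name) for f in files]
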