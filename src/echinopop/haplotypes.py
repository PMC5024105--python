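"""Haplotype collapsing, minimum-spanning haplotype networks, and
synonymous / non-synonymous classification of substitutions.

The network is an epsilon-zero minimum-spanning network: a minimum spanning
tree on Hamming distances augmented with every alternative edge that could
replace an MST edge at equal weight.  Substitutions are classified against
the most frequent haplotype under the invertebrate mitochondrial genetic
code, appropriate for a mitochondrial protein-coding fragment such as COI.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from echinopop.errors import ValidationError
from echinopop.io import SequencePanel

_MISSING_CHARS = frozenset("-N")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is a DataFrame (rows = haplotype labels H_1.., ordered by
    decreasing total count then first occurrence; columns = populations).
    ``sequences[label]`` maps a label to its nucleotide string.
    """

    sequences: dict[str, str]
    counts: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative haplotype count")
        if len(set(self.sequences.values())) != len(self.sequences):
            raise ValidationError("haplotypes not pairwise distinct")

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def most_frequent(self) -> str:
        return self.counts.index[0]

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def collapse_haplotypes(panel: SequencePanel) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with population counts.

    Ordering is deterministic: decreasing total count, ties broken by first
    occurrence in the panel.
    """
    pops = panel.populations()
    first_seen: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    for i, (sid, seq) in enumerate(zip(panel.sample_ids, panel.sequences)):
        if seq not in first_seen:
            first_seen[seq] = i
            counts[seq] = {p: 0 for p in pops}
        counts[seq][panel.population_of[sid]] += 1
    seqs = sorted(
        counts, key=lambda s: (-sum(counts[s].values()), first_seen[s])
    )
    labels = [f"H_{k + 1}" for k in range(len(seqs))]
    mat = pd.DataFrame(
        [[counts[s][p] for p in pops] for s in seqs], index=labels, columns=pops
    )
    return HaplotypeTable(sequences=dict(zip(labels, seqs)), counts=mat)


def hamming(seq_a: str, seq_b: str) -> int:
    """Pairwise-complete Hamming distance: sites with '-' or 'N' in either
    sequence are ignored."""
    return sum(
        a != b
        for a, b in zip(seq_a, seq_b)
        if a not in _MISSING_CHARS and b not in _MISSING_CHARS
    )


def _variable_sites(seq_a: str, seq_b: str) -> list[int]:
    return [
        i
        for i, (a, b) in enumerate(zip(seq_a, seq_b))
        if a != b and a not in _MISSING_CHARS and b not in _MISSING_CHARS
    ]


def build_network(table: HaplotypeTable) -> nx.Graph:
    """Epsilon-zero minimum-spanning network on Hamming distances.

    Includes every edge that appears in at least one minimum spanning tree
    (Kruskal with all tied-weight alternatives).  Edges of weight > 1 are
    flagged ``multi_step`` (the "red dash" convention for multi-mutation
    links).  Node attributes carry total haplotype frequency.
    """
    labels = table.labels
    g = nx.Graph()
    totals = table.total_counts()
    for lab in labels:
        g.add_node(lab, frequency=int(totals[lab]))
    if len(labels) == 1:
        return g
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            w = hamming(table.sequences[a], table.sequences[b])
            edges.append((w, a, b))
    # epsilon-0 MSN: process weights ascending over a union-find; keep every
    # current-weight edge joining two distinct components, then merge.
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges.sort(key=lambda e: (e[0], labels.index(e[1]), labels.index(e[2])))
    by_weight: dict[int, list] = {}
    for w, a, b in edges:
        by_weight.setdefault(w, []).append((a, b))
    for w in sorted(by_weight):
        batch = [(a, b) for a, b in by_weight[w] if find(a) != find(b)]
        for a, b in batch:
            g.add_edge(
                a,
                b,
                weight=w,
                multi_step=bool(w > 1),
                variable_sites=_variable_sites(table.sequences[a], table.sequences[b]),
            )
        for a, b in batch:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "from": a,
            "to": b,
            "steps": d["weight"],
            "multi_step": d["multi_step"],
            "variable_sites": ";".join(map(str, d["variable_sites"])),
        }
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["from", "to", "steps", "multi_step", "variable_sites"])


def write_network(g: nx.Graph, edge_csv_path=None, graphml_path=None) -> None:
    if edge_csv_path is not None:
        network_edge_table(g).to_csv(edge_csv_path, index=False)
    if graphml_path is not None:
        h = g.copy()
        for _, _, d in h.edges(data=True):
            d["variable_sites"] = ";".join(map(str, d["variable_sites"]))
        nx.write_graphml(h, graphml_path)


# ---------------------------------------------------------------------------
# synonymous / non-synonymous classification
# ---------------------------------------------------------------------------

_INVERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[5]


def _translate_codon(codon: str) -> str | None:
    if any(c in _MISSING_CHARS for c in codon):
        return None
    if codon in _INVERTEBRATE_MITO.stop_codons:
        return "*"
    return _INVERTEBRATE_MITO.forward_table[codon]


def classify_substitutions(
    table: HaplotypeTable, reading_frame_offset: int = 0
) -> pd.DataFrame:
    """Label each substitution relative to the most frequent haplotype.

    Codons are read from ``reading_frame_offset`` (0, 1 or 2) using the
    invertebrate mitochondrial code.  Sites falling before the offset, in an
    incomplete trailing codon, or in codons containing gaps/N are labelled
    ``untranslated`` and excluded from the non-synonymous count.

    Returns a DataFrame with one row per (haplotype, variable site) and a
    ``label`` in {synonymous, non-synonymous, untranslated}; the attribute
    ``df.attrs["n_non_synonymous"]`` gives the total non-synonymous count.
    """
    if reading_frame_offset not in (0, 1, 2):
        raise ValidationError("reading_frame_offset must be 0, 1 or 2")
    ref_label = table.most_frequent()
    ref = table.sequences[ref_label]
    L = len(ref)
    if L - reading_frame_offset < 3:
        raise ValidationError("alignment too short to translate a codon")
    rows = []
    for lab in table.labels:
        if lab == ref_label:
            continue
        alt = table.sequences[lab]
        for site in _variable_sites(ref, alt):
            rel = site - reading_frame_offset
            if rel < 0:
                label, ref_aa, alt_aa = "untranslated", None, None
            else:
                cstart = reading_frame_offset + 3 * (rel // 3)
                if cstart + 3 > L:
                    label, ref_aa, alt_aa = "untranslated", None, None
                else:
                    ref_codon = ref[cstart:cstart + 3]
                    pos_in_codon = site - cstart
                    alt_codon = (
                        ref_codon[:pos_in_codon] + alt[site] + ref_codon[pos_in_codon + 1:]
                    )
                    ref_aa = _translate_codon(ref_codon)
                    alt_aa = _translate_codon(alt_codon)
                    if ref_aa is None or alt_aa is None:
                        label = "untranslated"
                    elif ref_aa == alt_aa:
                        label = "synonymous"
                    else:
                        label = "non-synonymous"
            rows.append(
                {
                    "haplotype": lab,
                    "site": site,
                    "ref_base": ref[site],
                    "alt_base": alt[site],
                    "ref_aa": ref_aa,
                    "alt_aa": alt_aa,
                    "label": label,
                }
            )
    df = pd.DataFrame(
        rows, columns=["haplotype", "site", "ref_base", "alt_base", "ref_aa", "alt_aa", "label"]
    )
    df.attrs["n_non_synonymous"] = int((df["label"] == "non-synonymous").sum()) if len(df) else 0
    return df
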