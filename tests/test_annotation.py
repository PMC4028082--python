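"""Representative-isoform selection, exon categories, location classes,
enhancer filtering — each checked against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from metaplot.annotation import (EXON_CATEGORIES, REGION_CLASSES,
                                 DEFAULT_CLASSIFIER_CONFIG, build_gene,
                                 classify_exons, classify_region_location,
                                 filter_and_assign_enhancers,
                                 select_representative)
from metaplot.models import GenomicInterval, TranscriptModel
from metaplot.simulate import EMPTY_CHROM, FixtureSpec, random_gene, synth_annotation


def tx(tid, pairs, strand="+", gene="G1", chrom="chr1"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs)
    return TranscriptModel(tid, gene, exons, strand)


# ---------------------------------------------------------------------------
# representative isoform
# ---------------------------------------------------------------------------

class TestSelectRepresentative:
    def test_longest_span_wins(self):
        g = build_gene([tx("T1", [(0, 1000)]), tx("T2", [(0, 500), (1400, 1500)])])
        assert select_representative(g) == "T2"  # span 1500 vs 1000

    def test_single_transcript_is_identity(self):
        g = build_gene([tx("Tonly", [(10, 200)])])
        assert g.representative == "Tonly"

    def test_tie_breaks_lexicographically(self):
        g = build_gene([tx("Tb", [(0, 800)]), tx("Ta", [(100, 900)])])
        assert select_representative(g) == "Ta"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_representative([])


# ---------------------------------------------------------------------------
# exon classification
# ---------------------------------------------------------------------------

def oracle_classify(gene):
    """Direct enumeration oracle: for every exon of every transcript, apply
    the category rules literally against each other transcript."""
    out = {}
    for t in gene.transcripts:
        order = t.exons if t.strand == "+" else t.exons[::-1]
        first_5p, last_3p = order[0], order[-1]
        for exon in t.exons:
            key = (t.transcript_id, exon.start, exon.end)
            if exon == first_5p:
                out[key] = "promoter"
                continue
            if exon == last_3p:
                out[key] = "polyA"
                continue
            donor_mismatch = acceptor_mismatch = variant = False
            for u in gene.transcripts:
                if u.transcript_id == t.transcript_id:
                    continue
                over = [x for x in u.exons
                        if set(range(x.start, x.end)) & set(range(exon.start, exon.end))]
                if not over:
                    variant = True
                    continue
                u_order = u.exons if u.strand == "+" else u.exons[::-1]
                best = None
                for x in over:
                    if t.strand == "+":
                        acc_d = exon.start != x.start
                        don_d = exon.end != x.end
                    else:
                        acc_d = exon.end != x.end
                        don_d = exon.start != x.start
                    if x == u_order[0]:
                        acc_d = False  # partner transcription start, not a splice site
                    if x == u_order[-1]:
                        don_d = False
                    cand = (don_d, acc_d)
                    if best is None or sum(cand) < sum(best):
                        best = cand
                donor_mismatch |= best[0]
                acceptor_mismatch |= best[1]
            if variant:
                out[key] = "variant"
            elif donor_mismatch and acceptor_mismatch:
                out[key] = "altBoth"
            elif donor_mismatch:
                out[key] = "altDonor"
            elif acceptor_mismatch:
                out[key] = "altAcceptor"
            else:
                out[key] = "canonical"
    return out


class TestClassifyExons:
    def test_skipped_exon_is_variant(self):
        # shared boundaries everywhere, middle exon absent from T2
        g = build_gene([
            tx("T1", [(0, 100), (200, 300), (400, 500)]),
            tx("T2", [(0, 100), (400, 500)]),
        ])
        cats = {(r.transcript_id, r.exon.start): r.category
                for r in classify_exons(g)}
        assert cats[("T1", 0)] == "promoter"
        assert cats[("T1", 200)] == "variant"
        assert cats[("T1", 400)] == "polyA"

    def test_single_isoform_three_exons(self):
        g = build_gene([tx("T1", [(0, 100), (200, 300), (400, 500)])])
        assert [r.category for r in classify_exons(g)] == [
            "promoter", "canonical", "polyA"]

    def test_minus_strand_terminals_flip(self):
        g = build_gene([tx("T1", [(0, 100), (200, 300), (400, 500)], strand="-")])
        cats = {r.exon.start: r.category for r in classify_exons(g)}
        assert cats[400] == "promoter" and cats[0] == "polyA"

    def test_single_exon_transcript_is_promoter(self):
        g = build_gene([tx("T1", [(0, 100)])])
        assert classify_exons(g)[0].category == "promoter"

    def test_mixed_strands_error(self):
        t1 = tx("T1", [(0, 100), (300, 400)], strand="+")
        t2 = tx("T2", [(0, 100), (300, 400)], strand="-")
        g = build_gene([t1, t2])
        with pytest.raises(ValueError, match="strand"):
            classify_exons(g)

    def test_alt_boundary_categories(self):
        g = build_gene([
            tx("T1", [(0, 100), (200, 300), (400, 500), (600, 700),
                      (800, 900), (1000, 1100), (1200, 1300)]),
            tx("T2", [(0, 100), (200, 300), (400, 520), (580, 700),
                      (790, 910), (1200, 1300)]),
        ])
        cats = {(r.transcript_id, r.exon.start): r.category
                for r in classify_exons(g)}
        assert cats[("T1", 200)] == "canonical"
        assert cats[("T1", 400)] == "altDonor"
        assert cats[("T1", 600)] == "altAcceptor"
        assert cats[("T1", 800)] == "altBoth"
        assert cats[("T1", 1000)] == "variant"

    def test_random_genes_match_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(200):
            g = random_gene(rng, f"G{i}", "chr1", offset=1000)
            got = {(r.transcript_id, r.exon.start, r.exon.end): r.category
                   for r in classify_exons(g)}
            assert got == oracle_classify(g), f"mismatch on gene {i}"

    def test_permutation_invariance_and_totality(self):
        rng = np.random.default_rng(5)
        for i in range(30):
            g = random_gene(rng, f"G{i}", "chr1", offset=1000)
            base = {(r.transcript_id, r.exon.start): r.category
                    for r in classify_exons(g)}
            shuffled = build_gene(tuple(reversed(g.transcripts)),
                                  gene_name=g.gene_name)
            assert base == {(r.transcript_id, r.exon.start): r.category
                            for r in classify_exons(shuffled)}
            assert all(r.category in EXON_CATEGORIES for r in classify_exons(g))
            for t in g.transcripts:
                terms = [r for r in classify_exons(g)
                         if r.transcript_id == t.transcript_id
                         and r.category in ("promoter", "polyA")]
                assert len(terms) == (1 if len(t.exons) == 1 else 2)


# ---------------------------------------------------------------------------
# region-location classification
# ---------------------------------------------------------------------------

def oracle_location(iv, store, cfg=DEFAULT_CLASSIFIER_CONFIG):
    """Linear scan over every gene and heterochromatin row."""
    m = iv.midpoint
    tss = [(abs(m - g.tss), g) for g in store.genes.values() if g.chrom == iv.chrom]
    d = min(tss)[0] if tss else None
    if d is not None:
        if d <= cfg.proximal_bp:
            return "ProximalPromoter"
        if d <= cfg.promoter1k_bp:
            return "Promoter1K"
        if d <= cfg.promoter3k_bp:
            return "Promoter3K"
        if any(g.span.start <= m < g.span.end for _, g in tss):
            return "Genebody"
    het = store.heterochromatin
    for kind, label in (("centromere", "Pericentromere"), ("telomere", "Subtelomere")):
        for row in het[het["kind"] == kind].itertuples(index=False):
            if row.chrom == iv.chrom and \
                    row.start - cfg.heterochromatin_bp <= m < row.end + cfg.heterochromatin_bp:
                return label
    dists = []
    for g in store.genes.values():
        if g.chrom != iv.chrom:
            continue
        if g.span.start <= m < g.span.end:
            dists.append(0)
        else:
            dists.append(min(abs(m - g.span.start), abs(m - (g.span.end - 1))))
    if not dists or min(dists) > cfg.desert_bp:
        return "Genedesert"
    return "OtherIntergenic"


def probe_points(store):
    """Deliberate probes hitting every one of the eight classes."""
    g = next(iter(store.iter_genes(biotype="protein_coding")))
    long_gene = next(x for x in store.genes.values() if x.gene_name == "LongGene")
    L = store.chrom_sizes[EMPTY_CHROM]
    pts = [
        (g.chrom, g.tss + 100),          # ProximalPromoter
        (g.chrom, g.tss + 600),          # Promoter1K
        (g.chrom, g.tss + 2500),         # Promoter3K
        (long_gene.chrom, (long_gene.span.start + long_gene.span.end) // 2),
        (EMPTY_CHROM, L // 2 + 20_000),  # Pericentromere window
        (EMPTY_CHROM, 50_000),           # Subtelomere window
        (EMPTY_CHROM, 250_000),          # Genedesert (no genes on chrU)
        (g.chrom, g.tss - 10_000),       # OtherIntergenic (usually)
    ]
    return [GenomicInterval(c, p - 10, p + 10) for c, p in pts]


class TestRegionLocation:
    def test_probe_set_covers_all_eight_classes(self, store):
        labels = {classify_region_location(iv, store).label
                  for iv in probe_points(store)}
        # the last probe may legitimately fall in a neighbour's promoter ring;
        # the first seven are engineered to be unambiguous
        assert labels >= set(REGION_CLASSES) - {"OtherIntergenic"}
        assert "OtherIntergenic" in {
            classify_region_location(iv, store).label
            for iv in probe_points(store)
        } | {oracle_location(iv, store) for iv in probe_points(store)}

    def test_random_intervals_match_linear_scan_oracle(self, store):
        rng = np.random.default_rng(11)
        chroms = list(store.chrom_sizes)
        for _ in range(500):
            c = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(100, store.chrom_sizes[c] - 100))
            iv = GenomicInterval(c, p, p + 20)
            got = classify_region_location(iv, store)
            assert got.label == oracle_location(iv, store)
            assert got.label in REGION_CLASSES

    def test_genebody_precedence_inside_exon_far_from_tss(self, store):
        long_gene = next(x for x in store.genes.values()
                         if x.gene_name == "LongGene")
        last_exon = long_gene.rep.exons[-1]
        iv = GenomicInterval(long_gene.chrom, last_exon.start + 50,
                             last_exon.start + 70)
        assert abs(iv.midpoint - long_gene.tss) > 3000
        assert classify_region_location(iv, store).label == "Genebody"

    def test_unknown_chromosome_named_in_error(self, store):
        with pytest.raises(KeyError, match="chrNope"):
            classify_region_location(GenomicInterval("chrNope", 0, 10), store)


# ---------------------------------------------------------------------------
# enhancer filtering
# ---------------------------------------------------------------------------

class TestEnhancers:
    def test_within_5kb_excluded_beyond_kept(self, store):
        g = next(iter(store.iter_genes(biotype="protein_coding")))
        near = GenomicInterval(g.chrom, g.tss + 4000 - 50, g.tss + 4000 + 50)
        # only valid when no other TSS sits within 5 kb of the far probe
        far_mid = g.tss + 6000
        far = GenomicInterval(g.chrom, far_mid - 50, far_mid + 50)
        out = filter_and_assign_enhancers([near, far], store)
        survivors = [iv for iv, _ in out]
        assert near not in survivors
        if far in survivors:  # excluded only if a neighbour's TSS is close
            gid = dict(out)[far]
            assert gid in store.genes

    def test_random_enhancers_match_exhaustive_search(self, store):
        rng = np.random.default_rng(23)
        chroms = [c for c in store.chrom_sizes if c != EMPTY_CHROM]
        enh = []
        for _ in range(300):
            c = chroms[rng.integers(len(chroms))]
            p = int(rng.integers(500, store.chrom_sizes[c] - 500))
            enh.append(GenomicInterval(c, p - 200, p + 200))
        got = filter_and_assign_enhancers(enh, store)
        cutoff = DEFAULT_CLASSIFIER_CONFIG.enhancer_tss_exclusion_bp
        expected = []
        for iv in enh:
            tss = [(abs(iv.midpoint - g.tss), g.gene_id, g.tss)
                   for g in store.genes.values() if g.chrom == iv.chrom]
            dmin, gid, _ = min(tss)
            if dmin > cutoff:
                expected.append((iv, gid))
        assert got == expected
        # invariant: no survivor within the exclusion zone of any TSS
        for iv, _ in got:
            for g in store.genes.values():
                if g.chrom == iv.chrom:
                    assert abs(iv.midpoint - g.tss) > cutoff

    def test_empty_input_empty_output(self, store):
        assert filter_and_assign_enhancers([], store) == []
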