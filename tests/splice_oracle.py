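"""Brute-force splice-event oracle: exhaustive pairwise isoform comparison.

Independent reference implementation used to cross-check the catalogue-based
caller on small genes. Written as plain nested loops over isoform pairs,
followed by the run-merge, terminal and dedup rules.
"""

from __future__ import annotations

import numpy as np

from chronotome.io_formats import TranscriptModel


def oracle_events(isoforms, target) -> set[tuple[str, tuple[int, int], int]]:
    """All (type, span, merged_count) events of ``target`` vs its siblings."""
    others = [s for s in isoforms if s.transcript_id != target.transcript_id]
    strand = target.strand
    ex = target.exons
    n = len(ex)
    t_introns = [(a.end, b.start) for a, b in zip(ex, ex[1:])]
    internal_everywhere = {
        (e.start, e.end) for s in isoforms for e in s.exons[1:-1]
    }

    def holds_exon(lo, hi):
        return any(lo <= xs and xe <= hi for xs, xe in internal_everywhere)

    raw: dict[tuple[str, tuple[int, int]], int] = {}

    def put(etype, span, count=1):
        raw[(etype, span)] = max(raw.get((etype, span), 0), count)

    for s in others:
        s_ex = s.exons
        s_introns = [(a.end, b.start) for a, b in zip(s_ex, s_ex[1:])]

        # IR: internal target exon strictly contains an intron of the sibling
        for i in range(1, n - 1):
            for a, b in s_introns:
                if ex[i].start < a and b < ex[i].end:
                    put("IR", (a, b))

        # ES: target intron bounded by sibling exon boundaries with >=1
        # sibling exon strictly between them
        for a, b in t_introns:
            for i in range(len(s_ex)):
                for k in range(i + 2, len(s_ex)):
                    if s_ex[i].end == a and s_ex[k].start == b:
                        run = s_ex[i + 1 : k]
                        put("ES", (run[0].start, run[-1].end), len(run))

        # AA / AD: shared donor or acceptor, no whole internal exon in the
        # difference region, changed-side exon not terminal
        for j, (a, b) in enumerate(t_introns):
            for c, d in s_introns:
                if (a, b) == (c, d):
                    continue
                if strand == "+":
                    donor_same, acceptor_same = a == c, b == d
                else:
                    donor_same, acceptor_same = b == d, a == c
                if donor_same and not acceptor_same:
                    lo, hi = (min(b, d), max(b, d)) if strand == "+" else (min(a, c), max(a, c))
                    if holds_exon(lo, hi):
                        continue
                    acc_exon = j + 1 if strand == "+" else j
                    if acc_exon in (0, n - 1):
                        continue
                    put("AA", (a, b))
                elif acceptor_same and not donor_same:
                    lo, hi = (min(a, c), max(a, c)) if strand == "+" else (min(b, d), max(b, d))
                    if holds_exon(lo, hi):
                        continue
                    don_exon = j if strand == "+" else j + 1
                    if don_exon in (0, n - 1):
                        continue
                    put("AD", (a, b))

        # ME: matching outer flank boundaries, disjoint runs, gene-wide
        # exactly-one condition
        for ai in range(n):
            for bi in range(ai + 2, n):
                for p in range(len(s_ex)):
                    for q in range(p + 2, len(s_ex)):
                        if ex[ai].end != s_ex[p].end or ex[bi].start != s_ex[q].start:
                            continue
                        own = ex[ai + 1 : bi]
                        sib = s_ex[p + 1 : q]
                        if any(
                            x.start < y.end and y.start < x.end
                            for x in own
                            for y in sib
                        ):
                            continue
                        own_set = {(e.start, e.end) for e in own}
                        sib_set = {(e.start, e.end) for e in sib}
                        ok = True
                        for t in isoforms:
                            tset = {(e.start, e.end) for e in t.exons}
                            has_own = own_set <= tset and not (sib_set & tset)
                            has_sib = sib_set <= tset and not (own_set & tset)
                            if not (has_own or has_sib):
                                ok = False
                                break
                        if ok:
                            span = (
                                min(own[0].start, sib[0].start),
                                max(own[-1].end, sib[-1].end),
                            )
                            put("ME", span, len(own))

    return {(etype, span, count) for (etype, span), count in raw.items()}


def random_gene(rng: np.random.Generator, gene_id: str = "g") -> list[TranscriptModel]:
    """Random small gene: <=4 isoforms derived from a base exon ladder."""
    n_exons = int(rng.integers(2, 9))
    pos = int(rng.integers(0, 1000))
    base = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 201))
        base.append((pos, pos + length))
        pos += length + int(rng.integers(100, 301))
    strand = "+" if rng.integers(2) == 0 else "-"

    def perturb(exons):
        exons = list(exons)
        op = rng.choice(["drop", "merge", "shift", "swap", "none"])
        if op == "drop" and len(exons) >= 3:
            i = int(rng.integers(1, len(exons) - 1))
            del exons[i]
        elif op == "merge" and len(exons) >= 2:
            i = int(rng.integers(0, len(exons) - 1))
            exons[i] = (exons[i][0], exons[i + 1][1])
            del exons[i + 1]
        elif op == "shift" and len(exons) >= 2:
            i = int(rng.integers(0, len(exons)))
            delta = int(rng.integers(10, 41))
            s, e = exons[i]
            if rng.integers(2) == 0 and i + 1 < len(exons):
                # move this exon's end (donor side on +) inward
                if e - delta > s:
                    exons[i] = (s, e - delta)
            elif i > 0:
                if s + delta < e:
                    exons[i] = (s + delta, e)
        elif op == "swap" and len(exons) >= 3:
            # replace an internal exon with a disjoint one in the same gap
            i = int(rng.integers(1, len(exons) - 1))
            s, e = exons[i]
            room = exons[i + 1][0] - e
            if room > 80:
                off = int(rng.integers(20, room - 60))
                exons[i] = (e + off, e + off + 50)
        return exons

    n_iso = int(rng.integers(1, 5))
    isoforms = [
        TranscriptModel.from_coords(f"{gene_id}.1", gene_id, "chr1", strand, base)
    ]
    for i in range(2, n_iso + 1):
        alt = perturb(perturb(base))
        isoforms.append(
            TranscriptModel.from_coords(f"{gene_id}.{i}", gene_id, "chr1", strand, alt)
        )
    return isoforms
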