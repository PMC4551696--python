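"""Independent slow oracles used by the test suite.

Everything here is deliberately naive: list-walking coordinate maps,
quadratic representation enumeration, a hardcoded codon table, and a
predicate-by-predicate classifier. None of it shares code paths with the
package implementation it checks.
"""

from __future__ import annotations

CODON_TABLE = {
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

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_translate(seq: str) -> str:
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def walk_transcript(tx):
    """Brute-force base-by-base walk in transcription order.

    Returns ``(t_of_g, label_of_g)`` where ``t_of_g`` maps every exonic
    genomic position to its 1-based spliced index and ``label_of_g`` maps
    every position of the span to ``(kind, base, offset, anchor)``.
    """
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    ordered = []  # genomic positions in transcription order, exonic only
    for s, e in exons:
        rng = range(s, e + 1) if tx.strand == "+" else range(e, s - 1, -1)
        ordered.extend(rng)
    t_of_g = {g: i + 1 for i, g in enumerate(ordered)}
    cds_start_t = t_of_g[tx.coding_start]
    cds_end_t = t_of_g[tx.coding_end]

    def coding_label(t):
        if t < cds_start_t:
            return "utr5", cds_start_t - t
        if t > cds_end_t:
            return "utr3", t - cds_end_t
        return "cds", t - cds_start_t + 1

    label = {}
    for g, t in t_of_g.items():
        kind, base = coding_label(t)
        label[g] = (kind, base, 0, kind)
    # introns, in transcription order
    for i in range(len(exons) - 1):
        if tx.strand == "+":
            lo, hi = exons[i][1] + 1, exons[i + 1][0] - 1
            positions = list(range(lo, hi + 1))
        else:
            lo, hi = exons[i + 1][1] + 1, exons[i][0] - 1
            positions = list(range(hi, lo - 1, -1))  # transcription order
        n = len(positions)
        prev_last_g = positions[0] - 1 if tx.strand == "+" else positions[0] + 1
        next_first_g = positions[-1] + 1 if tx.strand == "+" else positions[-1] - 1
        for j, g in enumerate(positions):
            d_up, d_down = j + 1, n - j
            if d_up <= d_down:
                akind, abase = coding_label(t_of_g[prev_last_g])
                label[g] = ("intron", abase, d_up, akind)
            else:
                akind, abase = coding_label(t_of_g[next_first_g])
                label[g] = ("intron", abase, -d_down, akind)
    return t_of_g, label


def oracle_cds(tx, reference) -> str:
    t_of_g, label = walk_transcript(tx)
    bases = []
    for g, t in sorted(t_of_g.items(), key=lambda kv: kv[1]):
        kind, base, _off, _a = label[g]
        if kind == "cds":
            b = reference.fetch(tx.chrom, g, g)
            bases.append(b if tx.strand == "+" else _COMP[b])
    return "".join(bases)


def brute_force_representations(seq: str, variant):
    """Quadratic enumeration: every placement whose edit equals the target.

    ``seq`` starts at genomic position 1. Returns sorted (pos, ref, alt).
    """
    if variant.vtype == "Deletion":
        i = variant.pos - 1
        target = seq[:i] + seq[i + len(variant.ref) :]
        L = len(variant.ref)
        out = []
        for p in range(0, len(seq) - L + 1):
            if seq[:p] + seq[p + L :] == target:
                out.append((p + 1, seq[p : p + L], ""))
        return sorted(out)
    if variant.vtype == "Insertion":
        i = variant.pos  # insertion after this many leading bases
        target = seq[:i] + variant.alt + seq[i:]
        L = len(variant.alt)
        out = []
        for p in range(0, len(seq) + 1):
            cand = target[p : p + L]
            if seq[:p] + cand + seq[p:] == target:
                out.append((p, "", cand))
        return sorted(out)
    return [(variant.pos, variant.ref, variant.alt)]


# -- slow, predicate-by-predicate classifier --------------------------------

CLASS_ORDER = [
    "SG", "ESS", "SS5", "SS", "EE", "FS", "IM", "SL", "IF", "NSY", "SY", "INT", "5PU", "3PU",
]


def oracle_facts(tx, variant, reference, label=None, cds=None):
    """Consequence facts from full edited-CDS retranslation (naive).

    Supports substitutions and pure indels placed anywhere in the span.
    """
    if label is None:
        _t, label = walk_transcript(tx)
    if cds is None:
        cds = oracle_cds(tx, reference)
    L = len(cds)
    is_ins = variant.vtype == "Insertion"
    if is_ins:
        flanks = [variant.pos, variant.pos + 1]
        if tx.strand == "-":
            flanks = flanks[::-1]
        labels = [label[g] for g in flanks]
        kinds = [l[0] for l in labels]
        fully_cds = kinds == ["cds", "cds"]
        boundary_cds = "cds" in kinds and "intron" in kinds
        coding = fully_cds or boundary_cds
        net = len(variant.alt) if coding else 0
        cds_positions = []
    else:
        gs = range(variant.pos, variant.pos + len(variant.ref))
        order = gs if tx.strand == "+" else reversed(list(gs))
        labels = [label[g] for g in order]
        cds_positions = [b for k, b, o, _a in labels if k == "cds" and o == 0]
        coding = bool(cds_positions)
        net = 0 if variant.vtype == "Substitution" else -len(cds_positions)
    frameshift = coding and variant.vtype != "Substitution" and net % 3 != 0
    start_lost = stop_lost = stop_gained = aa_changed = synonymous = False

    def tx_base(b):
        return b if tx.strand == "+" else _COMP[b]

    if coding and variant.vtype == "Substitution":
        c = cds_positions[0]
        edited = cds[: c - 1] + tx_base(variant.alt) + cds[c:]
        p_ref, p_alt = oracle_translate(cds), oracle_translate(edited)
        idx = (c - 1) // 3
        start_lost = idx == 0
        if not start_lost:
            aa_r, aa_a = p_ref[idx], p_alt[idx]
            if aa_r == "*":
                stop_lost = aa_a != "*"
                synonymous = aa_a == "*"
                aa_changed = aa_a != "*"
            else:
                stop_gained = aa_a == "*"
                synonymous = aa_r == aa_a
                aa_changed = aa_r != aa_a
    elif coding and not frameshift:
        if is_ins and kinds == ["cds", "cds"]:
            c5 = labels[0][1]
            edited = cds[:c5] + tx_base_seq(variant.alt, tx.strand) + cds[c5:]
        elif not is_ins and len(cds_positions) == len(variant.ref):
            c1, c2 = min(cds_positions), max(cds_positions)
            edited = cds[: c1 - 1] + cds[c2:]
        else:
            edited = None
        start_lost = bool(set(cds_positions) & {1, 2, 3}) or (
            is_ins and coding and labels[0][0] == "cds" and labels[0][1] in (1, 2)
        )
        if edited is not None:
            p_alt = oracle_translate(edited)
            stop_idx = p_alt.find("*")
            stop_gained = 0 <= stop_idx < len(edited) // 3 - 1
            stop_lost = stop_idx < 0
        else:
            stop_lost = bool(set(cds_positions) & {L - 2, L - 1, L})
    elif coding:  # frameshift
        start_lost = bool(set(cds_positions) & {1, 2, 3}) or (
            is_ins and labels[0][0] == "cds" and labels[0][1] in (1, 2)
        )
        stop_lost = bool(set(cds_positions) & {L - 2, L - 1, L})
        if is_ins and labels[0][0] == "cds":
            stop_lost = labels[0][1] in (L - 2, L - 1)
    return {
        "labels": labels,
        "coding": coding,
        "net": net,
        "frameshift": frameshift,
        "start_lost": start_lost,
        "stop_lost": stop_lost,
        "stop_gained": stop_gained,
        "aa_changed": aa_changed,
        "synonymous": synonymous,
        "is_ins": is_ins,
    }


def tx_base_seq(seq, strand):
    return seq if strand == "+" else oracle_revcomp(seq)


def oracle_classify(tx, variant, reference, label=None, cds=None, t_of_g=None):
    """First satisfied predicate in list order, each tested independently."""
    if label is None or t_of_g is None:
        t_of_g, label = walk_transcript(tx)
    facts = oracle_facts(tx, variant, reference, label=label, cds=cds)
    labels = facts["labels"]
    offsets = [o for _k, _b, o, _a in labels if o != 0]
    is_ins = facts["is_ins"]

    def alters(offset_set):
        if is_ins:
            return len(offsets) == 2 and all(o in offset_set for o in offsets)
        return any(o in offset_set for o in offsets)

    # exon-edge windows (first/last 3 bases of intron-adjacent exon edges)
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    windows = []
    cum = 0
    for i, (s, e) in enumerate(exons):
        n = e - s + 1
        if i > 0:
            windows.append((cum + 1, min(cum + 3, cum + n)))
        if i < len(exons) - 1:
            windows.append((max(cum + 1, cum + n - 2), cum + n))
        cum += n
    if is_ins:
        gs = [variant.pos, variant.pos + 1]
        ts = [t_of_g.get(g) for g in gs]
        in_windows = (
            None not in ts and any(a <= ts[0] <= b and a <= ts[1] <= b for a, b in windows)
        )
    else:
        ts = [t_of_g[g] for g in range(variant.pos, variant.pos + len(variant.ref)) if g in t_of_g]
        in_windows = any(a <= t <= b for t in ts for a, b in windows)

    exonic_kinds = {k for k, _b, o, _a in labels if o == 0}
    all_intronic = all(o != 0 for _k, _b, o, _a in labels)

    checks = [
        ("SG", variant.vtype == "Substitution" and facts["stop_gained"]),
        ("ESS", alters({1, 2, -1, -2})),
        ("SS5", alters({5})),
        ("SS", alters(set(range(1, 9)) | set(range(-8, 0)))),
        ("EE", not facts["frameshift"] and in_windows),
        ("FS", facts["frameshift"]),
        ("IM", facts["start_lost"]),
        ("SL", facts["stop_lost"]),
        ("IF", facts["coding"] and variant.vtype != "Substitution" and facts["net"] != 0),
        ("NSY", facts["coding"] and facts["aa_changed"]),
        ("SY", facts["coding"] and facts["synonymous"]),
        ("INT", all_intronic),
        ("5PU", not facts["coding"] and "utr5" in {k for k, *_ in labels}),
        ("3PU", not facts["coding"] and "utr3" in {k for k, *_ in labels}),
    ]
    for code, hit in checks:
        if hit:
            return code
    return None
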