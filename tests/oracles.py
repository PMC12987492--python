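"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain position-by-position loops straight from
the documented rules, deliberately sharing no code with the package beyond
its data containers.  Only meant for tiny instances.
"""

from __future__ import annotations

from tsscall.model import FORWARD


def oracle_step(values, strand, i):
    """Step height/factor at 1-based i on a dense value list."""
    e = lambda p: values[p - 1] if 1 <= p <= len(values) else 0.0
    prev = i - 1 if strand == FORWARD else i + 1
    height = e(i) - e(prev)
    if e(prev) > 0:
        factor = e(i) / e(prev)
    elif e(i) > 0:
        factor = float("inf")
    else:
        factor = 1.0
    return height, factor


def oracle_detect(values, strand, t_h, t_f):
    """All candidate positions with their metrics; zero-coverage never calls."""
    out = []
    for i in range(1, len(values) + 1):
        if values[i - 1] <= 0:
            continue
        height, factor = oracle_step(values, strand, i)
        if height >= t_h and factor >= t_f:
            out.append((i, height, factor))
    return out


def oracle_window_reduce(cands, window, mode, strand):
    """cands: [(pos, height, factor)] sorted; chain runs with gap <= window."""
    cands = sorted(cands)
    if window == 0 or len(cands) < 2:
        return cands
    runs, current = [], [cands[0]]
    for cand in cands[1:]:
        if cand[0] - current[-1][0] <= window:
            current.append(cand)
        else:
            runs.append(current)
            current = [cand]
    runs.append(current)
    survivors = []
    for run in runs:
        ordered = run if strand == FORWARD else list(reversed(run))
        if mode == "first":
            survivors.append(ordered[0])
        else:
            best = ordered[0]
            for cand in ordered[1:]:
                if cand[1] > best[1]:
                    best = cand
            survivors.append(best)
    return sorted(survivors)


def oracle_condition(tracks_by_rep, controls_by_rep, strand, p):
    """Detected+enriched TSS of one condition on one strand.

    tracks/controls: {replicate: dense value list}.  Returns
    [(pos, height, factor, det_count, ef)].
    """
    reduced_h = max(0.0, p.step_height - p.height_reduction)
    reduced_f = max(1.0, p.step_factor - p.factor_reduction)

    per_rep = {rep: oracle_window_reduce(
        oracle_detect(vals, strand, p.step_height, p.step_factor),
        p.window, p.reduction_mode, strand)
        for rep, vals in tracks_by_rep.items()}

    pool = sorted((pos, h, f, rep) for rep, cands in per_rep.items()
                  for pos, h, f in cands)
    if not pool:
        return []
    clusters, current = [], [pool[0]]
    for item in pool[1:]:
        if item[0] - current[-1][0] <= p.cross_replicate_shift:
            current.append(item)
        else:
            clusters.append(current)
            current = [item]
    clusters.append(current)

    detected = []
    for cluster in clusters:
        members = {}
        for pos, h, f, rep in cluster:
            if rep not in members or h > members[rep][1]:
                members[rep] = (pos, h, f)
        rep_pos, rep_h, rep_f = max(members.values(),
                                    key=lambda v: (v[1], -v[0]))
        for rep, vals in tracks_by_rep.items():
            if rep in members:
                continue
            best = None
            lo = max(1, rep_pos - p.cross_replicate_shift)
            hi = min(len(vals), rep_pos + p.cross_replicate_shift)
            for pos in range(lo, hi + 1):
                if vals[pos - 1] <= 0:
                    continue
                h, f = oracle_step(vals, strand, pos)
                if h >= reduced_h and f >= reduced_f and \
                        (best is None or h > best[1]):
                    best = (pos, h, f)
            if best is not None:
                members[rep] = best
        if len(members) < p.min_replicates:
            continue
        rep_pos, rep_h, rep_f = max(members.values(),
                                    key=lambda v: (v[1], -v[0]))
        efs = []
        for rep, vals in tracks_by_rep.items():
            e = vals[rep_pos - 1] if rep_pos <= len(vals) else 0.0
            c_vals = controls_by_rep[rep]
            c = c_vals[rep_pos - 1] if rep_pos <= len(c_vals) else 0.0
            if e <= 0 and c <= 0:
                continue
            efs.append(float("inf") if c == 0 else e / c)
        if not efs:
            continue
        ef = max(efs)
        if ef >= p.enrichment_factor:
            detected.append((rep_pos, rep_h, rep_f, len(members), ef))
    return detected


def oracle_cluster_conditions(by_condition, shift):
    """by_condition: {cond: [(pos, height, ...)]} one strand.  Returns
    [(representative_pos, {cond: pos})]."""
    pool = sorted((entry[0], cond, entry) for cond, entries
                  in by_condition.items() for entry in entries)
    if not pool:
        return []
    clusters, current = [], [pool[0]]
    for item in pool[1:]:
        if item[0] - current[-1][0] <= shift:
            current.append(item)
        else:
            clusters.append(current)
            current = [item]
    clusters.append(current)

    out = []
    for cluster in clusters:
        per_cond = {}
        for pos, cond, entry in cluster:
            if cond not in per_cond or entry[1] > per_cond[cond][1]:
                per_cond[cond] = entry
        rep_entry = max(per_cond.values(), key=lambda e: (e[1], -e[0]))
        out.append((rep_entry[0], {c: e[0] for c, e in per_cond.items()}))
    return out


def oracle_classify(position, strand, heights_by_tss, genes, p):
    """Class set of one TSS by checking every gene directly.

    heights_by_tss: {(pos, strand): strength} of *all* TSS, needed to settle
    the primary/secondary competition per gene.
    """
    classes = set()
    for gene in genes:
        same = strand == gene.strand
        if same and gene.start <= position <= gene.end:
            classes.add("internal")
        if not same:
            if gene.start <= position <= gene.end:
                classes.add("antisense")
            elif position < gene.start and gene.start - position <= p.antisense_distance:
                classes.add("antisense")
            elif position > gene.end and position - gene.end <= p.antisense_distance:
                classes.add("antisense")
        if same:
            if gene.strand == FORWARD:
                d = gene.start - position
            else:
                d = position - gene.end
            if 0 < d <= p.utr_length:
                # competition: strongest upstream TSS of this gene wins,
                # ties toward the smaller UTR distance
                rivals = []
                for (pos2, strand2), strength in heights_by_tss.items():
                    if strand2 != gene.strand:
                        continue
                    d2 = (gene.start - pos2 if gene.strand == FORWARD
                          else pos2 - gene.end)
                    if 0 < d2 <= p.utr_length:
                        rivals.append((strength, -d2, pos2))
                best = max(rivals)
                mine = (heights_by_tss[(position, strand)], -d, position)
                classes.add("primary" if mine == best else "secondary")
    if not classes:
        classes.add("orphan")
    return classes
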