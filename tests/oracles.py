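"""Independent brute-force enumerators of the segregation rules.

These re-derive mode compatibility from explicit per-member constraint
tables over genotype symbols, independently of the package's filter code,
so the two can be compared exhaustively.  Genotypes are the strings
``RR`` (hom-ref), ``RA`` (het), ``AA`` (hom-alt) and ``..`` (missing).
"""

from __future__ import annotations

GTS = ("RR", "RA", "AA", "..")


def _members_by_id(members):
    return {m["id"]: m for m in members}


def _affected_trio_children(members):
    ids = {m["id"] for m in members}
    return [
        m
        for m in members
        if m["affected"] and m.get("father") in ids and m.get("mother") in ids
    ]


def _parents_present(member, ids):
    out = []
    for key in ("father", "mother"):
        pid = member.get(key)
        if pid in ids:
            out.append(pid)
    return out


def oracle_segregates(
    mode: str,
    chrom: str,
    gts: dict[str, str],
    members: list[dict],
    dps: dict[str, int | None] | None = None,
    min_dp: int | None = 6,
    tolerate: bool = False,
) -> bool:
    """Mode compatibility by explicit rule enumeration (no package code)."""
    dps = dps or {}
    ids = {m["id"] for m in members}

    def present(mid):  # genotype known?
        return gts[mid] != ".."

    if mode == "dominant_denovo":
        if not _affected_trio_children(members):
            raise ValueError("no affected member with both parents")
        allowed = {True: {"RA", "AA"}, False: {"RR"}}
        for m in members:
            if not present(m["id"]):
                if tolerate:
                    continue
                return False
            if gts[m["id"]] not in allowed[m["affected"]]:
                return False
        for m in members:
            if not m["affected"]:
                continue
            for pid in _parents_present(m, ids):
                if min_dp is None:
                    continue
                dp = dps.get(pid)
                if dp is None:
                    if not tolerate:
                        return False
                elif dp < min_dp:
                    return False
        return True

    if mode == "dominant_inherited":
        allowed = {True: {"RA", "AA"}, False: {"RR"}}
        for m in members:
            if not present(m["id"]):
                if tolerate:
                    continue
                return False
            if gts[m["id"]] not in allowed[m["affected"]]:
                return False
        return True

    if mode == "recessive_homozygous":
        allowed = {True: {"AA"}, False: {"RR", "RA"}}
        for m in members:
            if not present(m["id"]):
                if tolerate:
                    continue
                return False
            if gts[m["id"]] not in allowed[m["affected"]]:
                return False
        for m in members:
            if not m["affected"]:
                continue
            for pid in _parents_present(m, ids):
                if not present(pid):
                    if tolerate:
                        continue
                    return False
                if gts[pid] != "RA":
                    return False
        return True

    if mode == "x_linked":
        if chrom.removeprefix("chr") != "X":
            return False
        for m in members:
            if m["affected"] and m["sex"] == "unknown":
                raise ValueError("affected member of unknown sex")
        by_id = _members_by_id(members)
        for m in members:
            g = gts[m["id"]]
            if g == "..":
                if tolerate:
                    continue
                return False
            if m["affected"]:
                if g != "AA":
                    return False
                if m["sex"] == "male":
                    fid, mid_ = m.get("father"), m.get("mother")
                    if fid in by_id:
                        fg = gts[fid]
                        if fg == "..":
                            if not tolerate:
                                return False
                        elif fg != "RR":
                            return False
                    if mid_ in by_id:
                        mg = gts[mid_]
                        if mg == "..":
                            if not tolerate:
                                return False
                        elif mg != "RA":
                            return False
            else:
                if m["sex"] == "male":
                    if g != "RR":
                        return False
                elif g == "AA":
                    return False
        return True

    raise ValueError(f"unknown mode {mode}")


def oracle_comphet_pairs(
    site_gts: dict[str, dict[str, str]],
    members: list[dict],
    genes: dict[str, str],
    tolerate: bool = False,
) -> set[frozenset]:
    """Trans pairs by exhaustive origin-assignment enumeration.

    ``site_gts``: site key -> {member id -> genotype symbol};
    ``genes``: site key -> gene.
    """
    children = _affected_trio_children(members)
    if not children:
        raise ValueError("no affected child with both parents")

    def origin_set(key, child):
        cg = site_gts[key][child["id"]]
        if cg == "..":
            if not tolerate:
                return set()
        elif cg != "RA":
            return set()
        fg = site_gts[key][child["father"]]
        mg = site_gts[key][child["mother"]]

        def carries(g):
            if g == "..":
                return {True, False} if tolerate else set()
            return {g in ("RA", "AA")}

        f, m = carries(fg), carries(mg)
        out = set()
        if True in f and False in m:
            out.add("P")
        if True in m and False in f:
            out.add("M")
        return out

    keys = list(site_gts)
    pairs: set[frozenset] = set()
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if genes[a] != genes[b]:
                continue
            ok = True
            for ch in children:
                oa, ob = origin_set(a, ch), origin_set(b, ch)
                if not any(
                    x != y and x in oa and y in ob
                    for x in ("P", "M")
                    for y in ("P", "M")
                ):
                    ok = False
                    break
            if ok:
                pairs.add(frozenset((a, b)))
    return pairs
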