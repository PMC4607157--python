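"""Tag classification: known-miRNA isomiRs, star-arm (new) miRNAs, moRNAs.

A kept tag aligned to an extended hairpin is first tested as an isomiR of an
annotated mature (exact / 1-2 nt shorter-longer at either end / same-length
1-2 substitution variants). Remaining tags are grouped into read clusters by
interval overlap; a cluster at the predicted star arm of a single-mature
hairpin becomes a new miRNA, a cluster mostly outside mature territory
becomes a miRNA-offset RNA (moRNA) on the 5' or 3' arm.

Star-arm prediction uses a maximum-base-pairing fold of the hairpin (Nussinov
dynamic program; AU/CG/GU pairs, minimum loop 3, ties broken toward pairs
closer to the hairpin ends), mapping each mature position across its pairing
partner and imposing the canonical 2-nt 3' overhang on both duplex ends.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .align import MappingVerdict, ReferenceIndex, TagAlignment
from .reference import ExtendedHairpin, HairpinRecord, MatureAnnotation

MAX_END_OFFSET = 2  # beyond this a variant is no longer an isomiR
STAR_TOLERANCE = 3  # nt tolerance matching a cluster 5' end to the star 5' end
MIN_CLUSTER_COUNT = 10  # reuses the ground-noise threshold
MIN_PAIRED_FRACTION = 0.5

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


@dataclasses.dataclass
class IsomiRRecord:
    mature_id: str
    category: str  # exact | shorter_longer | mismatch1 | mismatch2
    region: str  # 5p_end | 3p_end | both | none
    tag: str
    delta5: int
    delta3: int
    mismatch_positions: tuple[int, ...] = ()


@dataclasses.dataclass
class SmallRNAFeature:
    feature_id: str
    klass: str  # known_miRNA | new_miRNA | moRNA
    hairpin_id: str
    arm: str
    interval: tuple[int, int]  # extended-local
    representative: str
    tags: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class Catalogue:
    features: list[SmallRNAFeature]
    isomirs: list[IsomiRRecord]
    unassigned: dict[str, str]  # tag -> reason
    star_intervals: dict[str, tuple[int, int]]  # hairpin_id -> extended-local

    def meta_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": f.feature_id,
                "class": f.klass,
                "hairpin_id": f.hairpin_id,
                "arm": f.arm,
                "start": f.interval[0],
                "end": f.interval[1],
                "sequence": f.representative,
            }
            for f in self.features
        ]
        return pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame(
            columns=["class", "hairpin_id", "arm", "start", "end", "sequence"]
        )


# ---------------------------------------------------------------------------
# secondary structure

def max_pairing_fold(seq: str) -> list[int | None]:
    """Pairing partners under a maximum-base-pairing fold (Nussinov DP).

    Returns, for each position, the partner index or None. Allowed pairs are
    AU, CG and GU (on the DNA alphabet: A-T, C-G, G-T); hairpin loops span at
    least 3 unpaired bases. Traceback prefers pairing the outermost bases, so
    ties resolve toward pairs closer to the sequence ends.
    """
    n = len(seq)
    pairs: list[int | None] = [None] * n
    if n < 5:
        return pairs
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 4, n):
            if (seq[i], seq[j]) in _PAIRS:
                can[i, j] = True
    M = np.zeros((n, n), dtype=np.int32)
    for d in range(4, n):
        i = np.arange(0, n - d)
        j = i + d
        best = np.maximum(M[i + 1, j], M[i, j - 1])
        best = np.maximum(best, M[i + 1, j - 1] + can[i, j])
        for t in range(1, d):
            best = np.maximum(best, M[i, i + t] + M[i + t + 1, j])
        M[i, j] = best

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 4:
            continue
        if can[i, j] and M[i, j] == M[i + 1, j - 1] + 1:
            pairs[i], pairs[j] = j, i
            stack.append((i + 1, j - 1))
        elif M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
        elif M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for t in range(1, j - i):
                if M[i, i + t] + M[i + t + 1, j] == M[i, j]:
                    stack.append((i, i + t))
                    stack.append((i + t + 1, j))
                    break
    return pairs


def predict_star_interval(
    hairpin: HairpinRecord, mature: MatureAnnotation
) -> tuple[int, int] | None:
    """Hairpin-local interval of the expected star-arm product, or None.

    Each mature position is mapped across its base-pairing partner; the
    spanning partner interval, shifted by the canonical 2-nt 3' overhang on
    both duplex ends, is the star. Returns None when fewer than half of the
    mature bases are paired or the result collapses onto the mature itself.
    """
    pairs = max_pairing_fold(hairpin.sequence)
    s, e = mature.interval
    partners = [pairs[x] for x in range(s, e) if pairs[x] is not None]
    if len(partners) < MIN_PAIRED_FRACTION * (e - s):
        return None
    lo, hi = min(partners), max(partners)
    star = (max(0, lo + 2), min(len(hairpin.sequence), hi + 3))
    if star[1] - star[0] < 10:
        return None
    if star[0] < e and star[1] > s:  # overlaps the mature: degenerate fold
        return None
    return star


# ---------------------------------------------------------------------------
# isomiR classification

def classify_isomir(
    alignment: TagAlignment, mature: MatureAnnotation, mature_interval: tuple[int, int]
) -> IsomiRRecord | None:
    """Classify an ungapped hairpin hit against one mature annotation.

    ``mature_interval`` is the mature's interval in the same (extended-local)
    coordinates as the alignment. Returns None for tags that are not isomiRs
    of this mature: no overlap, end offsets beyond 2 nt, or mismatches
    combined with shifted ends.
    """
    L = len(alignment.tag)
    ms, me = mature_interval
    p = alignment.position
    if p + L <= ms or p >= me:
        return None
    d5 = p - ms
    d3 = (p + L) - me
    mm = alignment.mismatches
    if mm == 0:
        if d5 == 0 and d3 == 0:
            return IsomiRRecord(mature.mature_id, "exact", "none", alignment.tag, 0, 0)
        if max(abs(d5), abs(d3)) <= MAX_END_OFFSET:
            if d5 != 0 and d3 != 0:
                region = "both"
            elif d5 != 0:
                region = "5p_end"
            else:
                region = "3p_end"
            return IsomiRRecord(
                mature.mature_id, "shorter_longer", region, alignment.tag, d5, d3
            )
        return None
    if mm <= 2 and d5 == 0 and d3 == 0:
        half = -(-L // 2)  # ceil(L/2); positions 0..half-1 are the 5' half
        in5 = any(pos < half for pos in alignment.mismatch_positions)
        in3 = any(pos >= half for pos in alignment.mismatch_positions)
        if in5 and in3:
            region = "both"
        elif in5:
            region = "5p_end"
        else:
            region = "3p_end"
        assert alignment.mismatch_positions, "mismatch category without positions"
        return IsomiRRecord(
            mature.mature_id,
            f"mismatch{mm}",
            region,
            alignment.tag,
            0,
            0,
            alignment.mismatch_positions,
        )
    return None


# ---------------------------------------------------------------------------
# read clusters: new miRNAs and moRNAs

def _cluster_by_overlap(
    items: list[tuple[str, int, int]]
) -> list[list[tuple[str, int, int]]]:
    """Group (tag, start, end) items by interval overlap, transitively."""
    items = sorted(items, key=lambda x: (x[1], x[2], x[0]))
    clusters: list[list[tuple[str, int, int]]] = []
    current: list[tuple[str, int, int]] = []
    reach = -1
    for item in items:
        if current and item[1] < reach:
            current.append(item)
            reach = max(reach, item[2])
        else:
            if current:
                clusters.append(current)
            current = [item]
            reach = item[2]
    if current:
        clusters.append(current)
    return clusters


def _fraction_outside(interval: tuple[int, int], blocks: list[tuple[int, int]]) -> float:
    lo, hi = interval
    covered = 0
    for s, e in blocks:
        covered += max(0, min(hi, e) - max(lo, s))
    return 1.0 - covered / (hi - lo)


def call_clusters(
    ext: ExtendedHairpin,
    leftovers: list[tuple[str, int, int]],  # (tag, start, end) extended-local
    tag_totals: pd.Series,
    star_interval: tuple[int, int] | None,
    star_name: str | None,
    min_cluster_count: int = MIN_CLUSTER_COUNT,
    star_tolerance: int = STAR_TOLERANCE,
) -> tuple[list[SmallRNAFeature], dict[str, str]]:
    """Turn non-isomiR tags on one extended hairpin into cluster features.

    Clusters overlapping the predicted star interval (representative 5' end
    within ``star_tolerance`` of the star 5' end) become new miRNAs; clusters
    whose representative has more than half of its bases outside mature and
    new-miRNA territory become moRNAs, one per arm (additional same-arm
    moRNAs are numbered). Cluster total count must reach
    ``min_cluster_count``.
    """
    matures = ext.mature_intervals_extended()
    features: list[SmallRNAFeature] = []
    unassigned: dict[str, str] = {}
    arm_seen: dict[str, int] = {}
    hp_suffix = ext.hairpin_id.split("-", 1)[1] if "-" in ext.hairpin_id else ext.hairpin_id
    by_arm = {m.arm: m for m in ext.hairpin.matures}

    # moRNAs can sit flush against the star product, so a read cluster that
    # merely touches it must not swallow it: tags whose 5' end matches the
    # predicted star 5' end form their own cluster.
    if star_interval is not None:
        star_members = [
            item for item in leftovers
            if abs(item[1] - star_interval[0]) <= star_tolerance
        ]
        others = [item for item in leftovers if item not in star_members]
        clusters = _cluster_by_overlap(others)
        if star_members:
            clusters.append(star_members)
    else:
        clusters = _cluster_by_overlap(leftovers)
    # classify most abundant clusters first so new-miRNA territory is known
    def cluster_total(cluster):
        return sum(tag_totals.get(t, 0) for t, _, _ in cluster)

    clusters.sort(key=lambda c: (-cluster_total(c), c[0][1]))
    miRNA_blocks = list(matures.values())

    for cluster in clusters:
        total = cluster_total(cluster)
        rep_tag, rep_start, rep_end = max(
            cluster,
            key=lambda item: (tag_totals.get(item[0], 0), item[2] - item[1], item[0]),
        )
        tags = sorted({t for t, _, _ in cluster})
        if total < min_cluster_count:
            for t in tags:
                unassigned[t] = "cluster_below_count_floor"
            continue
        if all(
            s >= ms and e <= me
            for _, s, e in cluster
            for ms, me in [_enclosing(matures, (s, e))]
            if ms is not None
        ) and _enclosing(matures, (rep_start, rep_end))[0] is not None:
            warnings.warn(
                f"cluster inside mature interval on {ext.hairpin_id}; "
                "reassigning as isomiR territory",
                stacklevel=2,
            )
            for t in tags:
                unassigned[t] = "inside_mature_interval"
            continue
        if (
            star_interval is not None
            and abs(rep_start - star_interval[0]) <= star_tolerance
        ):
            feat = SmallRNAFeature(
                feature_id=f"{star_name}*",
                klass="new_miRNA",
                hairpin_id=ext.hairpin_id,
                arm=_arm_of((rep_start, rep_end), ext, by_arm),
                interval=(rep_start, rep_end),
                representative=rep_tag,
                tags=tags,
            )
            features.append(feat)
            miRNA_blocks.append(star_interval)
            continue
        if _fraction_outside((rep_start, rep_end), miRNA_blocks) > 0.5:
            arm = _arm_of((rep_start, rep_end), ext, by_arm)
            arm_seen[arm] = arm_seen.get(arm, 0) + 1
            suffix = "" if arm_seen[arm] == 1 else f"-{arm_seen[arm]}"
            features.append(
                SmallRNAFeature(
                    feature_id=f"moR-{hp_suffix}-{arm}{suffix}",
                    klass="moRNA",
                    hairpin_id=ext.hairpin_id,
                    arm=arm,
                    interval=(rep_start, rep_end),
                    representative=rep_tag,
                    tags=tags,
                )
            )
            continue
        for t in tags:
            unassigned[t] = "ambiguous_cluster"
    return features, unassigned


def _enclosing(
    matures: dict[str, tuple[int, int]], interval: tuple[int, int]
) -> tuple[int | None, int | None]:
    for ms, me in matures.values():
        if interval[0] >= ms and interval[1] <= me:
            return ms, me
    return None, None


def _arm_of(
    interval: tuple[int, int],
    ext: ExtendedHairpin,
    by_arm: dict[str, MatureAnnotation],
) -> str:
    """5' or 3' arm of a cluster: at/upstream of the 5p mature start -> 5p,
    at/downstream of the 3p mature end -> 3p, else by hairpin midpoint."""
    mid = (interval[0] + interval[1]) / 2
    off = ext.offset
    if "5p" in by_arm and mid <= by_arm["5p"].interval[0] + off:
        return "5p"
    if "3p" in by_arm and mid >= by_arm["3p"].interval[1] + off:
        return "3p"
    return "5p" if mid < len(ext.sequence) / 2 else "3p"


# ---------------------------------------------------------------------------
# full catalogue

def annotate(
    index: ReferenceIndex,
    verdicts: dict[str, MappingVerdict],
    tag_counts: pd.DataFrame,
    min_cluster_count: int = MIN_CLUSTER_COUNT,
    star_tolerance: int = STAR_TOLERANCE,
) -> Catalogue:
    """Build the feature catalogue from kept tags.

    Each kept tag is assigned to its best hairpin hit (fewest mismatches,
    then lexicographic hairpin id, then position), classified as an isomiR of
    an overlapping mature if possible, and otherwise fed to cluster analysis
    on that hairpin. Every tag ends up in exactly one feature or in the
    unassigned map with a reason.
    """
    isomirs: list[IsomiRRecord] = []
    unassigned: dict[str, str] = {}
    star_intervals: dict[str, tuple[int, int]] = {}
    per_hairpin: dict[str, list[TagAlignment]] = {}
    tag_totals = tag_counts.sum(axis=1)

    order = sorted(verdicts)
    for tag in order:
        verdict = verdicts[tag]
        if verdict.status != "kept":
            unassigned[tag] = verdict.status
            continue
        if not verdict.hairpin_hits:
            unassigned[tag] = "no_hairpin_hit"
            continue
        best = min(
            verdict.hairpin_hits, key=lambda h: (h.mismatches, h.target, h.position)
        )
        per_hairpin.setdefault(best.target, []).append(best)

    features: list[SmallRNAFeature] = []
    known: dict[str, SmallRNAFeature] = {}
    for hid in sorted(per_hairpin):
        ext = index.extended[hid]
        hp = ext.hairpin
        matures_ext = ext.mature_intervals_extended()
        by_id = {m.mature_id: m for m in hp.matures}

        star = None
        star_name = None
        if len(hp.matures) == 1:
            star_local = predict_star_interval(hp, hp.matures[0])
            if star_local is not None:
                star = (star_local[0] + ext.offset, star_local[1] + ext.offset)
                star_intervals[hid] = star
                star_name = hp.matures[0].mature_id

        leftovers: list[tuple[str, int, int]] = []
        for hit in per_hairpin[hid]:
            record = None
            for mid, minterval in matures_ext.items():
                record = classify_isomir(hit, by_id[mid], minterval)
                if record is not None:
                    break
            if record is None:
                leftovers.append((hit.tag, hit.position, hit.position + len(hit.tag)))
                continue
            isomirs.append(record)
            mat = by_id[record.mature_id]
            feat = known.get(record.mature_id)
            if feat is None:
                feat = SmallRNAFeature(
                    feature_id=record.mature_id,
                    klass="known_miRNA",
                    hairpin_id=hid,
                    arm=mat.arm,
                    interval=matures_ext[record.mature_id],
                    representative=mat.sequence,
                    tags=[],
                )
                known[record.mature_id] = feat
                features.append(feat)
            feat.tags.append(record.tag)

        cluster_feats, cluster_unassigned = call_clusters(
            ext,
            leftovers,
            tag_totals,
            star,
            star_name,
            min_cluster_count=min_cluster_count,
            star_tolerance=star_tolerance,
        )
        features.extend(cluster_feats)
        unassigned.update(cluster_unassigned)

    # representative = most abundant member tag
    for feat in features:
        if feat.tags:
            feat.representative = max(
                feat.tags, key=lambda t: (tag_totals.get(t, 0), len(t), t)
            )
    return Catalogue(
        features=features,
        isomirs=isomirs,
        unassigned=unassigned,
        star_intervals=star_intervals,
    )
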