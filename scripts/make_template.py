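"""Generate the synthetic 468-point landmark template shipped with roipulse.

Three stages:
1. ROI anchor centers start on a schematic face layout and are spaced by a
   spring pass so regions sharing keypoints sit adjacent (target distance
   shrinks with the length of the shared vertex chain) and unrelated regions
   do not collide.
2. Keypoints used by the 28 polygons relax toward regular m-gon targets on
   each ROI's fixed anchor circle with one global winding direction (the
   table's vertex orders come from a planar mesh, so shared chains are
   traversed oppositely by the two regions); shared points take the
   least-squares average, with a circular phase refit each sweep.
3. Validation on rasterized even-odd masks (the operative criterion for the
   renderer round trip): every ROI >= 30 pixels, pairwise mask overlap <= 2
   pixels.  shapely simplicity is reported as a diagnostic.

Run from repo root:  python scripts/make_template.py
"""
import itertools
import json
import sys

import numpy as np
from shapely.geometry import Polygon

sys.path.insert(0, "src")
from roipulse.roi_scheme import (  # noqa: E402
    N_LANDMARKS,
    FaceMeshFrame,
    load_roi_table,
    polygon_mask,
)

H = W = 256
MIN_PIXELS = 30
OVERLAP_TOL_PX = 2
OVERLAP_TOL_AREA = 1.0  # px^2, geometric

SCHEMATIC = {
    1: (128, 30), 2: (70, 44), 3: (186, 44), 4: (128, 72),
    5: (128, 104), 6: (128, 130), 7: (128, 158), 8: (96, 158),
    9: (160, 158), 10: (128, 144), 11: (102, 136), 12: (154, 136),
    13: (106, 112), 14: (150, 112), 15: (128, 180), 16: (106, 188),
    17: (150, 188), 18: (84, 176), 19: (172, 176), 20: (34, 90),
    21: (222, 90), 22: (66, 128), 23: (190, 128), 24: (62, 180),
    25: (194, 180), 26: (128, 226), 27: (92, 210), 28: (164, 210),
}


def radii(rois, scale):
    return {r.index_k: scale * (4.0 + 0.95 * len(r.keypoint_list)) for r in rois}


def adjacency(rois):
    adj = {}
    for a, b in itertools.combinations(rois, 2):
        shared = set(a.keypoint_list) & set(b.keypoint_list)
        if shared:
            adj[(a.index_k, b.index_k)] = len(shared)
    return adj


def space_centers(rois, rad, adj, iters=800):
    C = {r.index_k: np.array(SCHEMATIC[r.index_k], float) for r in rois}
    keys = [r.index_k for r in rois]
    for _ in range(iters):
        force = {k: np.zeros(2) for k in keys}
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = C[b] - C[a]
                dist = np.linalg.norm(d) + 1e-9
                u = d / dist
                if (a, b) in adj:
                    nshared = adj[(a, b)]
                    t = (rad[a] + rad[b]) * max(1.02 - 0.06 * (nshared - 1), 0.72)
                    err = dist - t
                    force[a] += 0.25 * err * u
                    force[b] -= 0.25 * err * u
                else:
                    t = 1.18 * (rad[a] + rad[b])
                    if dist < t:
                        err = dist - t
                        force[a] += 0.4 * err * u
                        force[b] -= 0.4 * err * u
        for k in keys:
            C[k] += 0.5 * force[k]
    return C


WINDING = -1.0  # one global winding; the table's shared edges are consistent


def circular_targets(pts, m, r, center):
    """Regular m-gon targets with one global winding."""
    ang = np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0])
    base = WINDING * 2 * np.pi * np.arange(m) / m
    phase = np.angle(np.mean(np.exp(1j * (ang - base))))
    theta = base + phase
    return center + r * np.column_stack([np.cos(theta), np.sin(theta)])


def solve_vertices(rois, C, rad, sweeps=4000):
    rng = np.random.default_rng(42)
    P = {}
    for r in rois:
        c = C[r.index_k]
        m = len(r.keypoint_list)
        theta = WINDING * 2 * np.pi * np.arange(m) / m
        tgt = c + rad[r.index_k] * np.column_stack([np.cos(theta), np.sin(theta)])
        for kp, t in zip(r.keypoint_list, tgt):
            P.setdefault(kp, []).append(t)
    P = {k: np.mean(v, axis=0) + rng.normal(0, 0.3, 2) for k, v in P.items()}
    for it in range(sweeps):
        pulls = {k: [] for k in P}
        for r in rois:
            kps = list(r.keypoint_list)
            pts = np.array([P[k] for k in kps])
            tgt = circular_targets(pts, len(kps), rad[r.index_k], C[r.index_k])
            for kp, t in zip(kps, tgt):
                pulls[kp].append(t)
        maxmove = 0.0
        for k in P:
            new = np.mean(pulls[k], axis=0)
            maxmove = max(maxmove, np.linalg.norm(new - P[k]))
            P[k] = 0.4 * P[k] + 0.6 * new
        if maxmove < 1e-5:
            print(f"  vertex relax converged at sweep {it}")
            break
    return P


def build_frame(P):
    points = np.full((N_LANDMARKS, 2), -1000.0)
    for k, v in P.items():
        points[k] = v
    return FaceMeshFrame(0, points)


def validate(rois, P):
    frame = build_frame(P)
    masks = {}
    polys = {}
    problems = []
    for r in rois:
        m = polygon_mask(frame, r, H, W)
        masks[r.index_k] = m.mask
        if m.pixel_count < MIN_PIXELS:
            problems.append(f"SMALL ROI {r.index_k} {r.name}: {m.pixel_count} px")
        pg = Polygon([tuple(P[k]) for k in r.keypoint_list])
        polys[r.index_k] = pg
        if not pg.is_valid:
            problems.append(f"NONSIMPLE ROI {r.index_k} {r.name}")
    keys = sorted(masks)
    worst = 0.0
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            inter = int((masks[a] & masks[b]).sum())
            area = (
                polys[a].intersection(polys[b]).area
                if polys[a].is_valid and polys[b].is_valid else OVERLAP_TOL_AREA + 1
            )
            worst = max(worst, float(inter), area)
            if inter > OVERLAP_TOL_PX or area > OVERLAP_TOL_AREA:
                problems.append(
                    f"OVERLAP ROI {a} vs {b}: {inter} px / {area:.2f} px^2"
                )
    return problems, worst


def repair(rois, P, rounds=60):
    """Pull short runs of exclusive vertices (flanked by shared ones) inward
    when their polygon overlaps the neighbour across the shared chain."""
    by_k = {r.index_k: r for r in rois}
    for _ in range(rounds):
        problems, _ = validate(rois, P)
        overlaps = [p for p in problems if p.startswith("OVERLAP")]
        if not overlaps:
            return P, problems
        for msg in overlaps:
            parts = msg.split()
            a, b = int(parts[2]), int(parts[4].rstrip(":"))
            for me, other in ((a, b), (b, a)):
                kps = list(by_k[me].keypoint_list)
                shared = set(kps) & set(by_k[other].keypoint_list)
                if not shared:
                    continue
                centroid = np.mean([P[k] for k in kps], axis=0)
                m = len(kps)
                for i, k in enumerate(kps):
                    if k in shared:
                        continue
                    prev_s = kps[(i - 1) % m] in shared
                    next_s = kps[(i + 1) % m] in shared
                    if prev_s or next_s:
                        P[k] = P[k] + 0.25 * (centroid - P[k]) / max(
                            np.linalg.norm(centroid - P[k]), 1e-9
                        ) * 4.0
    return P, validate(rois, P)[0]


def main():
    rois = load_roi_table()
    adj = adjacency(rois)
    print(f"{len(adj)} adjacent ROI pairs")
    best = None
    for scale in (1.0, 0.92, 0.85, 0.78, 0.7):
        rad = radii(rois, scale)
        C = space_centers(rois, rad, adj)
        P = solve_vertices(rois, C, rad)
        problems, worst = validate(rois, P)
        print(f"scale={scale}: {len(problems)} problems, worst overlap {worst} px")
        for p in problems[:15]:
            print("  " + p)
        if problems and all(p.startswith("OVERLAP") for p in problems):
            P, problems = repair(rois, P)
            print(f"  after repair: {len(problems)} problems")
        if not problems:
            best = P
            break
    if best is None:
        sys.exit(1)
    P = best

    used = sorted(P)
    allpts = np.array([P[k] for k in used])
    lo, hi = allpts.min(0), allpts.max(0)
    margin = 12.0
    s = min((W - 2 * margin) / (hi[0] - lo[0]), (H - 2 * margin) / (hi[1] - lo[1]))
    s = min(s, 1.0)
    for k in used:
        P[k] = (P[k] - (lo + hi) / 2) * s + np.array([W / 2, H / 2])

    problems, _ = validate(rois, P)
    assert not problems, problems

    points = np.zeros((N_LANDMARKS, 2))
    unused = [k for k in range(N_LANDMARKS) if k not in set(used)]
    for j, k in enumerate(unused):
        ang = 2 * np.pi * j / len(unused)
        points[k] = [W / 2 + 120 * np.cos(ang), H / 2 + 120 * np.sin(ang)]
    for k in used:
        points[k] = P[k]
    points = np.round(points, 2)

    out = {
        "description": (
            "synthetic 468-point face-mesh landmark template: procedurally "
            "relaxed schematic layout, not a detector output"
        ),
        "height": H,
        "width": W,
        "points": points.tolist(),
    }
    with open("src/roipulse/data/synthetic_face_template.json", "w") as fh:
        json.dump(out, fh)
    frame = build_frame({k: points[k] for k in used})
    counts = [polygon_mask(frame, r, H, W).pixel_count for r in rois]
    print(f"wrote template: {len(used)} used keypoints, "
          f"pixel counts {min(counts)}-{max(counts)}")


if __name__ == "__main__":
    main()
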