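"""Branching vessel-network generator with exact ground truth.

Vessels are grown as correlated random walks launched from the image edge,
branching stochastically, and rasterized as disks of fixed caliber. Walks
are self-avoiding at the vessel scale: a walker that comes within one
caliber of a foreign vessel terminates there (an anastomosis), so distinct
vessels do not silently merge into blobs — which keeps the planted
centerline an honest ground truth for skeleton-based morphometry.
``centerline_length_px`` counts the distinct rasterized centerline pixels,
i.e. the centerline's length in pixel units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import AnalysisError
from ..types import EnFaceAngiogram


@dataclass
class VesselTruth:
    """Ground truth for one generated network."""

    mask: np.ndarray              # exact binary vessel map
    centerline_mask: np.ndarray   # rasterized planted centerlines
    centerline_length_px: float   # distinct centerline pixels
    mean_caliber_px: float        # exact mean width: vessel px / centerline px
    density: float                # vessel pixels / total pixels, exact
    branch_count: int             # number of bifurcations


def _disk_offsets(diameter_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = diameter_px / 2.0
    ri = int(math.ceil(r))
    dr, dc = np.mgrid[-ri:ri + 1, -ri:ri + 1]
    keep = dr ** 2 + dc ** 2 <= r ** 2 + 1e-9
    return dr[keep], dc[keep]


def generate_vessel_network(
    size_px: int = 256,
    seed: int = 0,
    n_seeds: int = 6,
    step_persistence: float = 0.9,
    branch_prob: float = 0.02,
    caliber_px: float = 3.0,
    target_density: float = 0.35,
    noise_level: float = 0.05,
    vessel_intensity: float = 0.9,
    plexus: str = "SVP",
    eye_id: str = "",
    quality: float = 40.0,
    scale_um_per_px: float = 5.86,
    max_steps: int | None = None,
    initial_walker: tuple[float, float, float] | None = None,
    respawn: bool = True,
) -> tuple[EnFaceAngiogram, VesselTruth]:
    """Grow a vessel network until the mask reaches ``target_density``.

    Walkers start at random edge points heading inward; each step turns by a
    Gaussian angle of SD ``(1 − step_persistence)`` radians, advances one
    pixel, stamps a disk of diameter ``caliber_px``, and branches with
    probability ``branch_prob`` (the daughter departs at roughly ±60°).
    ``n_seeds`` walkers are launched initially; fresh edge seeds are added
    whenever all walkers have terminated before the target density is met.
    ``initial_walker`` (row, col, heading) pins the first walker for
    deterministic single-vessel scenarios. With ``respawn=False`` growth
    ends when the initial walkers and their branches have terminated, so
    density and complexity rise with ``branch_prob`` instead of being
    pinned at ``target_density``.

    Returns the angiogram (vessels at ``vessel_intensity`` over a dim noisy
    background; ``noise_level = 0`` gives a constant background) and the
    exact :class:`VesselTruth`. Raises if the target density cannot be
    reached within the step budget, reporting the density achieved.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    if not 0 <= branch_prob <= 1:
        raise ValueError("branch_prob must lie in [0,1]")
    if caliber_px < 1:
        raise ValueError("caliber_px must be >= 1")

    rng = np.random.default_rng(seed)
    mask = np.zeros((size_px, size_px), dtype=bool)
    centerline = np.zeros((size_px, size_px), dtype=bool)
    cl_owner = np.zeros((size_px, size_px), dtype=np.int32)
    # territory grid: which walker last claimed the neighbourhood of a
    # centerline pixel; stepping into foreign territory ends the walk
    territory = np.zeros((size_px, size_px), dtype=np.int32)
    d_rows, d_cols = _disk_offsets(caliber_px)
    sep = caliber_px + 1.0
    t_rows, t_cols = _disk_offsets(2.0 * sep)
    grace_steps = int(2 * math.ceil(sep))
    turn_sd = max(0.0, 1.0 - step_persistence)
    total_px = size_px * size_px
    target_px = int(math.ceil(target_density * total_px))
    if max_steps is None:
        max_steps = 60 * total_px // max(int(caliber_px), 1)

    def spawn_walker(walker_id: int) -> list | None:
        # edge seeds first; once the border fills, seed in free interior
        # space (capillary beds are fed from out-of-plane anyway)
        for _ in range(20):
            if rng.random() < 0.5:
                side = rng.integers(4)
                u = rng.uniform(0, size_px)
                if side == 0:
                    pos = [0.0, u, rng.normal(math.pi / 2, 0.3)]
                elif side == 1:
                    pos = [size_px - 1.0, u, rng.normal(-math.pi / 2, 0.3)]
                elif side == 2:
                    pos = [u, 0.0, rng.normal(0.0, 0.3)]
                else:
                    pos = [u, size_px - 1.0, rng.normal(math.pi, 0.3)]
            else:
                pos = [rng.uniform(0, size_px), rng.uniform(0, size_px),
                       rng.uniform(-math.pi, math.pi)]
            ri = min(int(round(pos[0])), size_px - 1)
            ci = min(int(round(pos[1])), size_px - 1)
            if territory[ri, ci] != 0:
                continue
            # state: [row, col, theta, id, grace, joining_countdown]
            return pos + [walker_id, 0, -1]
        return None

    join_steps = int(math.ceil(sep))
    next_id = 1
    walkers: list[list] = []
    if initial_walker is not None:
        walkers.append(list(initial_walker) + [next_id, 0, -1])
    else:
        for _ in range(n_seeds):
            next_id += 1
            w = spawn_walker(next_id)
            if w is not None:
                walkers.append(w)

    vessel_px = 0
    centerline_px = 0
    steps = 0
    iterations = 0
    branch_count = 0
    while vessel_px < target_px:
        iterations += 1
        if iterations >= max_steps:
            raise AnalysisError(
                f"target density {target_density} unreachable in step budget; "
                f"achieved {vessel_px / total_px:.4f}"
            )
        if not walkers:
            if not respawn:
                break
            next_id += 1
            w = spawn_walker(next_id)
            if w is None:
                continue
            walkers.append(w)
        w = walkers[-1]
        if turn_sd > 0:
            w[2] += rng.normal(0.0, turn_sd)
        r = w[0] + math.sin(w[2])
        c = w[1] + math.cos(w[2])
        if not (0 <= r < size_px and 0 <= c < size_px):
            walkers.pop()
            continue
        ri = min(int(round(r)), size_px - 1)
        ci = min(int(round(c)), size_px - 1)
        if w[5] >= 0:        # joining a neighbour: run straight, then stop
            if w[5] == 0:
                walkers.pop()
                continue
            w[5] -= 1
        elif w[4] > 0:       # post-branch grace: skip the proximity check
            w[4] -= 1
        else:
            # the territory stamp has radius ~one caliber, so testing the
            # prospective point alone enforces centerline separation; on
            # contact the vessel anastomoses into the neighbour instead of
            # stopping short of it, which leaves no free tip behind
            owner = territory[ri, ci]
            if owner != 0 and owner != w[3]:
                # steer toward the nearest foreign centerline pixel
                win = 7
                r0, r1 = max(ri - win, 0), min(ri + win + 1, size_px)
                c0, c1 = max(ci - win, 0), min(ci + win + 1, size_px)
                local = centerline[r0:r1, c0:c1] \
                    & (territory[r0:r1, c0:c1] != w[3])
                targets = np.argwhere(local)
                if len(targets):
                    dr = targets[:, 0] + r0 - w[0]
                    dc = targets[:, 1] + c0 - w[1]
                    k = int(np.argmin(dr ** 2 + dc ** 2))
                    w[2] = math.atan2(float(dr[k]), float(dc[k]))
                    w[5] = int(math.ceil(math.hypot(dr[k], dc[k]))) + 1
                    r = w[0] + math.sin(w[2])
                    c = w[1] + math.cos(w[2])
                    if not (0 <= r < size_px and 0 <= c < size_px):
                        walkers.pop()
                        continue
                    ri = min(int(round(r)), size_px - 1)
                    ci = min(int(round(c)), size_px - 1)
                else:
                    w[5] = join_steps
        w[0], w[1] = r, c
        rr = np.clip(ri + d_rows, 0, size_px - 1)
        cc = np.clip(ci + d_cols, 0, size_px - 1)
        flat = np.unique(rr * size_px + cc)  # clipping can duplicate indices
        vessel_px += int((~mask.flat[flat]).sum())
        mask.flat[flat] = True
        # pixels inside the merge zone of a foreign centerline (branch
        # take-offs, anastomosis run-ins) add no skeleton length of their
        # own and are excluded from the planted length
        jr0, jr1 = max(ri - 1, 0), min(ri + 2, size_px)
        jc0, jc1 = max(ci - 1, 0), min(ci + 2, size_px)
        owners = cl_owner[jr0:jr1, jc0:jc1]
        foreign_near = np.any((owners != 0) & (owners != w[3]))
        if not centerline[ri, ci] and not foreign_near:
            centerline[ri, ci] = True
            cl_owner[ri, ci] = w[3]
            centerline_px += 1
        tr = np.clip(ri + t_rows, 0, size_px - 1)
        tc = np.clip(ci + t_cols, 0, size_px - 1)
        patch = territory[tr, tc]
        territory[tr, tc] = np.where(patch == 0, w[3], patch)
        steps += 1
        if branch_prob > 0 and rng.random() < branch_prob:
            next_id += 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            walkers.insert(0, [w[0], w[1],
                               w[2] + sign * rng.normal(math.pi / 3, 0.15),
                               next_id, grace_steps, -1])
            branch_count += 1

    density = mask.sum() / total_px
    if noise_level > 0:
        background = np.clip(rng.normal(0.08, noise_level, mask.shape),
                             0.0, 0.45)
    else:
        background = np.full(mask.shape, 0.08)
    pixels = np.where(mask, vessel_intensity, background)
    angiogram = EnFaceAngiogram(
        pixels=pixels, scale_x=scale_um_per_px, scale_y=scale_um_per_px,
        plexus=plexus, eye_id=eye_id, quality=quality,
    )
    truth = VesselTruth(
        mask=mask.copy(), centerline_mask=centerline.copy(),
        centerline_length_px=float(centerline_px),
        mean_caliber_px=float(vessel_px) / max(centerline_px, 1),
        density=float(density),
        branch_count=branch_count,
    )
    return angiogram, truth
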