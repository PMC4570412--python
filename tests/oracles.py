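"""Independent brute-force reference implementations.

Plain-Python (loop-based, no vectorization) versions of the preprocessing and
feature primitives, written directly from their definitions.  Tests compare
the package's implementations against these on random inputs.
"""

import math


def median_filter_ref(series, window):
    """Sliding median with boundary replication, by sorting each window."""
    n = len(series)
    half = window // 2
    out = []
    for i in range(n):
        win = []
        for k in range(i - half, i + half + 1):
            k = min(max(k, 0), n - 1)  # replicate boundary samples
            win.append(series[k])
        win.sort()
        out.append(win[len(win) // 2])
    return out


def joint_angle_ref(s, i):
    dot = sum(a * b for a, b in zip(s, i))
    return math.acos(max(-1.0, min(1.0, dot)))


def rotation_range_ref(z_channel, window):
    filt = median_filter_ref(list(z_channel), window)
    return max(filt) - min(filt)


def smoothness_ref(accel_rows, window):
    total = 0.0
    for axis in range(3):
        raw = [row[axis] for row in accel_rows]
        filt = median_filter_ref(raw, window)
        total += sum(abs(r - f) for r, f in zip(raw, filt))
    return total


def movement_amount_ref(timestamps, gyro_rows, rest_window=0.5):
    n = len(timestamps)
    rest_idx = [i for i in range(n) if timestamps[i] <= timestamps[0] + rest_window]
    total = 0.0
    for axis in range(3):
        mags = [abs(row[axis]) for row in gyro_rows]
        rest = sorted(mags[i] for i in rest_idx)
        k = len(rest)
        baseline = rest[k // 2] if k % 2 else 0.5 * (rest[k // 2 - 1] + rest[k // 2])
        excess = [max(0.0, m - baseline) for m in mags]
        for i in range(n - 1):
            dt = timestamps[i + 1] - timestamps[i]
            total += 0.5 * (excess[i] + excess[i + 1]) * dt
    return total


def grip_strength_ref(values, window):
    return max(median_filter_ref(list(values), window))


def finger_state_ref(flexion_rows, mode, window):
    filt_cols = [
        median_filter_ref([row[c] for row in flexion_rows], window) for c in range(5)
    ]
    sums = [sum(col[i] for col in filt_cols) for i in range(len(flexion_rows))]
    best = 0
    for i in range(1, len(sums)):
        if (sums[i] > sums[best]) if mode == "flexion" else (sums[i] < sums[best]):
            best = i
    return [col[best] for col in filt_cols]


def normalize_speed_ref(wrist_positions, usable, threshold, target):
    """Two-stage resampling rule on wrist positions; returns retained indices.

    ``wrist_positions`` maps frame index -> (x, y, z); ``usable`` lists frame
    indices with a tracked wrist, in order.
    """

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))

    retained = [usable[0]]
    for i in usable[1:]:
        if dist(wrist_positions[i], wrist_positions[retained[-1]]) >= threshold:
            retained.append(i)
    n = len(retained)
    picks = []
    for j in range(target):
        # round-half-to-even to mirror IEEE rounding of the index map
        k = round(j * (n - 1) / (target - 1))
        picks.append(retained[k])
    return picks


def find_extreme_ref(heights, direction):
    """Exhaustive scan; ``heights`` is a list of (index, y) usable pairs."""
    best_i, best_y = heights[0]
    for i, y in heights[1:]:
        if (y > best_y) if direction == "highest" else (y < best_y):
            best_i, best_y = i, y
    return best_i
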