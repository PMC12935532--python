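"""Independent brute-force reference for the attribution hierarchy.

A literal per-pixel loop that re-derives the sequential rules from scratch
(no shared code with the vectorized implementation beyond the data types),
used as the oracle in equivalence tests.
"""

import numpy as np


def _score(desc):
    return (desc.spatial_score + desc.temporal_score
            + desc.explicitness_score) / 3.0


def brute_force_attribution(stack, registry, config):
    """Return (label, level, source) object grids, '' where no loss."""
    grid = stack.grid
    labels = np.full(grid.shape, "", dtype=object)
    levels = np.full(grid.shape, "", dtype=object)
    sources = np.full(grid.shape, None, dtype=object)

    loss = stack["loss_year"].values
    density = stack["density"].values
    plantation = stack["plantation"].values if "plantation" in stack else None
    fire = stack["fire_year"].values if "fire_year" in stack else None
    mode = config.attribution_mode

    order = {"commodity": 0, "land_use": 1, "mosaic": 2}
    scan = sorted(
        [(d, i) for i, d in enumerate(registry) if d.level in order],
        key=lambda di: (order[di[0].level], -_score(di[0]), di[1]),
    )
    drivers = sorted(
        [(d, i) for i, d in enumerate(registry) if d.level == "driver"],
        key=lambda di: (-_score(di[0]), di[1]),
    )
    fire_src = next((d.id for d in registry if d.level == "fire"), None)
    loss_src = next((d.id for d in registry if d.level == "loss"), None)

    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            t = loss[r, c]
            if t < grid.year_start or t > grid.year_end:
                continue
            is_forest = density[r, c] >= config.tcd_threshold
            if plantation is not None and mode != "full_statistical" \
                    and plantation[r, c] == 1:
                is_forest = False
            if not is_forest:
                labels[r, c] = "degradation_rotation"
                levels[r, c] = "none"
                continue
            claimed = False
            if mode == "full":
                for desc, _ in scan:
                    if desc.id not in stack:
                        continue
                    code = stack[desc.id].values[r, c]
                    if code == 0 or code == stack[desc.id].nodata:
                        continue
                    if desc.annual:
                        obs = stack[f"{desc.id}__year"].values[r, c]
                        ok = (t <= obs <= t + config.spatial_lag_years
                              and obs <= desc.last_valid_year)
                    else:
                        ok = t <= desc.last_valid_year
                    if ok:
                        labels[r, c] = desc.class_map[int(code)]
                        levels[r, c] = desc.level
                        sources[r, c] = desc.id
                        claimed = True
                        break
            if claimed:
                continue
            if mode != "full_statistical" and fire is not None:
                f = fire[r, c]
                if f > 0 and abs(f - t) <= config.fire_window_years:
                    labels[r, c] = "fire_non_commodity"
                    levels[r, c] = "fire"
                    sources[r, c] = fire_src
                    continue
            if mode != "full_statistical":
                done = False
                for desc, _ in drivers:
                    if desc.id not in stack:
                        continue
                    code = stack[desc.id].values[r, c]
                    if code == 0 or code == stack[desc.id].nodata:
                        continue
                    if t > desc.last_valid_year:
                        continue
                    raw = desc.class_map[int(code)]
                    if raw in ("commodity_driven", "shifting_agriculture"):
                        labels[r, c] = "unresolved_agriculture"
                        levels[r, c] = "driver"
                    elif raw == "forestry":
                        labels[r, c] = "forest_plantation"
                        levels[r, c] = "driver"
                    else:
                        labels[r, c] = "non_commodity_other"
                        levels[r, c] = "none"
                    sources[r, c] = desc.id
                    done = True
                    break
                if done:
                    continue
            labels[r, c] = "unattributed"
            levels[r, c] = "none"
            sources[r, c] = loss_src
    return labels, levels, sources
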