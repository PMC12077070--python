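"""Numba kernels for the spatial inner loops.

Foraging, home-range evaluation and the competitor census all walk the
same precomputed disc of cell offsets around a core cell, sorted by
centre distance with row-major tie-breaking so every walk is
deterministic.  The kernels operate on flat per-individual arrays; the
object-level API in :mod:`enercomm.behaviour` wraps them for single
individuals.

Distance accounting approximates central-place return trips: each cell
yielding intake contributes twice its centre distance to the daily path.
As an individual expands, the marginal locomotion cost of each trip is
added to its remaining foraging aim (converted to ingestion units), and
expansion stops when cumulative trip costs can no longer be paid from
storage plus the energy assimilated so far ("energy for movement
exhausted").
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from numba import njit

__all__ = ["ring_offsets", "forage_all", "evaluate_core",
           "competitor_census", "conspecific_census"]


@lru_cache(maxsize=8)
def ring_offsets(r_max: int):
    """Disc offsets within Euclidean radius ``r_max``, near-to-far.

    Returns ``(dr, dc, dist, disc_end)`` where ``disc_end[r]`` is the
    number of offsets with distance <= r (the disc area in cells).
    """
    items = []
    for dr in range(-r_max, r_max + 1):
        for dc in range(-r_max, r_max + 1):
            d = math.hypot(dr, dc)
            if d <= r_max + 1e-9:
                items.append((d, dr, dc))
    items.sort()
    dr = np.array([it[1] for it in items], dtype=np.int64)
    dc = np.array([it[2] for it in items], dtype=np.int64)
    dist = np.array([it[0] for it in items], dtype=np.float64)
    disc_end = np.array([int(np.searchsorted(dist, r + 1e-9, side="right"))
                         for r in range(r_max + 1)], dtype=np.int64)
    return dr, dc, dist, disc_end


@njit(cache=True)
def forage_all(res, habitat, toroidal, order, core_r, core_c, share, aim,
               max_off, storage, incr_kj_km, cell_km, intake_factor,
               off_dr, off_dc, off_dist,
               ingested, distance, scan_end, own_cells, forager_count,
               visits, visit_start, visit_end):
    """Sequential daily foraging of all individuals in the given order.

    ``aim`` is the remaining ingestion target [kJ ingested]; ``max_off``
    caps the number of disc offsets each individual may scan (home-range
    size limit).  ``scan_end`` reports the disc cells searched before a
    stop condition fired (the realised home-range size); cells whose yield
    cannot repay the trip are inspected but not harvested, so scarcity
    widens the searched range while harvesting stays economic.  ``res`` is
    depleted in place; ``forager_count`` counts foragers with intake per
    cell (competition census input).
    """
    side = res.shape[0]
    vp = 0
    for oi in range(order.shape[0]):
        i = order[oi]
        visit_start[i] = vp
        remaining = aim[i]
        ing = 0.0
        dist_cells = 0.0
        loco = 0.0
        nown = 0
        j = 0
        if remaining > 0.0:
            mo = max_off[i]
            while j < mo:
                rr = core_r[i] + off_dr[j]
                cc = core_c[i] + off_dc[j]
                j += 1
                if toroidal:
                    rr = rr % side
                    cc = cc % side
                elif rr < 0 or rr >= side or cc < 0 or cc >= side:
                    continue
                if not habitat[rr, cc]:
                    continue
                avail = res[rr, cc]
                if avail <= 1e-12:
                    continue
                d = off_dist[j - 1]
                marg = incr_kj_km[i] * 2.0 * d * cell_km
                # economic stop: skip cells whose assimilable yield cannot
                # repay the round trip (optimal central-place foraging)
                if d > 0.0 and avail * share[i] * intake_factor <= marg:
                    continue
                if loco + marg > storage[i] + intake_factor * ing + 1e-12:
                    break
                # the trip to this cell raises the day's needs before we harvest it
                if d > 0.0:
                    remaining += marg / intake_factor
                take = avail * share[i]
                if take > remaining:
                    take = remaining
                res[rr, cc] = avail - take
                ing += take
                remaining -= take
                if d > 0.0:
                    dist_cells += 2.0 * d
                    loco += marg
                forager_count[rr, cc] += 1
                if vp < visits.shape[0]:
                    visits[vp] = rr * side + cc
                    vp += 1
                nown += 1
                if remaining <= 1e-9:
                    break
        ingested[i] = ing
        distance[i] = dist_cells
        scan_end[i] = j
        own_cells[i] = nown
        visit_end[i] = vp


@njit(cache=True)
def evaluate_core(res, habitat, toroidal, r0, c0, share, need, max_off,
                  storage, incr_kj_km, cell_km, intake_factor,
                  off_dr, off_dc, off_dist):
    """Home-range evaluation around a candidate core (no depletion).

    Expands near-to-far accumulating accessible energy (share of each
    cell's standing resource) until ``need`` (ingestion units, inflated by
    marginal trip costs) is covered, the offset cap is hit, or movement
    energy runs out.  Returns the number of offsets scanned on success,
    -1 on failure.
    """
    side = res.shape[0]
    remaining = need
    gain = 0.0
    loco = 0.0
    j = 0
    if remaining <= 0.0:
        return 1
    while j < max_off:
        rr = r0 + off_dr[j]
        cc = c0 + off_dc[j]
        j += 1
        if toroidal:
            rr = rr % side
            cc = cc % side
        elif rr < 0 or rr >= side or cc < 0 or cc >= side:
            continue
        if not habitat[rr, cc]:
            continue
        avail = res[rr, cc]
        if avail <= 1e-12:
            continue
        d = off_dist[j - 1]
        marg = incr_kj_km * 2.0 * d * cell_km
        if d > 0.0 and avail * share * intake_factor <= marg:
            continue
        if loco + marg > storage + intake_factor * gain + 1e-12:
            return -1
        if d > 0.0:
            loco += marg
            remaining += marg / intake_factor
        g = avail * share
        gain += g
        remaining -= g
        if remaining <= 1e-9:
            return j
    return -1


@njit(cache=True)
def competitor_census(forager_count_flat, visits, visit_start, visit_end, out):
    """Mean number of other foragers per foraged patch, per individual.

    Averages (foragers on cell - 1) over the cells each individual
    actually harvested today.
    """
    for i in range(out.shape[0]):
        total = 0.0
        ncell = 0
        for v in range(visit_start[i], visit_end[i]):
            total += forager_count_flat[visits[v]]
            ncell += 1
        out[i] = (total / ncell - 1.0) if ncell > 0 else 0.0


@njit(cache=True)
def conspecific_census(species, rows, cols, side, radius, toroidal, counts):
    """Same-species neighbours within ``radius`` cells of each core."""
    n = species.shape[0]
    r2 = radius * radius
    for i in range(n):
        c = 0
        for j in range(n):
            if j == i or species[j] != species[i]:
                continue
            dr = abs(rows[i] - rows[j])
            dc = abs(cols[i] - cols[j])
            if toroidal:
                if side - dr < dr:
                    dr = side - dr
                if side - dc < dc:
                    dc = side - dc
            if dr * dr + dc * dc <= r2:
                c += 1
        counts[i] = c
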