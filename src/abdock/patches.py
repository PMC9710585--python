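"""Epitope surface patches that direct local docking.

Residues are visited by decreasing epitope probability; a residue seeds a
new patch only if its C-alpha lies at least ``min_center_sep`` from every
previously accepted center.  A patch collects every residue whose C-alpha
falls within ``radius`` of the center, so neighbouring patches overlap by
construction (radius 20 A > separation 10 A).  Patches are ranked by the
sum of member probabilities and only those reaching half the best sum are
retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EpitopePatch:
    center: tuple
    members: list
    summed_probability: float
    radius: float

    def __post_init__(self):
        if self.center not in self.members:
            raise ValueError("patch center must be one of its members")


def build_patches(
    probs: dict,
    ca_coords: dict,
    radius: float = 20.0,
    min_center_sep: float = 10.0,
    rsa: dict | None = None,
    min_rsa: float = 0.05,
    max_patches: int = 30,
) -> list[EpitopePatch]:
    """Greedy probability-ordered patch construction.

    Parameters
    ----------
    probs:
        Residue key -> epitope probability.
    ca_coords:
        Residue key -> C-alpha coordinate; must cover all keys in ``probs``.
    rsa:
        Optional residue key -> relative ASA; buried residues
        (RSA <= ``min_rsa``) cannot seed a patch but can still be members.

    Ties in probability are broken by input order of ``probs`` (lower
    residue index first).
    """
    if not probs:
        raise ValueError("empty probability map")
    missing = [k for k in probs if k not in ca_coords]
    if missing:
        raise ValueError(f"missing C-alpha coordinates for {missing[:3]}...")
    keys = list(probs)
    order = sorted(range(len(keys)), key=lambda i: (-probs[keys[i]], i))
    coords = {k: np.asarray(ca_coords[k], dtype=float) for k in keys}
    centers: list = []
    patches: list[EpitopePatch] = []
    for i in order:
        k = keys[i]
        if probs[k] <= 0:
            break
        if len(patches) >= max_patches:
            break
        if rsa is not None and rsa.get(k, 0.0) <= min_rsa:
            continue
        c = coords[k]
        if any(np.linalg.norm(c - coords[ck]) < min_center_sep for ck in centers):
            continue
        members = [m for m in keys if np.linalg.norm(coords[m] - c) <= radius]
        patches.append(
            EpitopePatch(
                center=k,
                members=members,
                summed_probability=float(sum(probs[m] for m in members)),
                radius=radius,
            )
        )
        centers.append(k)
    patches.sort(key=lambda p: (-p.summed_probability, keys.index(p.center)))
    return patches


def filter_patches(patches: list[EpitopePatch], keep_fraction: float = 0.5) -> list[EpitopePatch]:
    """Retain patches whose summed probability reaches ``keep_fraction`` of the best."""
    if not patches:
        raise ValueError("no patches to filter")
    best = max(p.summed_probability for p in patches)
    return [p for p in patches if p.summed_probability >= keep_fraction * best]


def patches_to_tsv(patches: list[EpitopePatch], path) -> None:
    pd.DataFrame(
        [
            {
                "center_chain": p.center[0],
                "center_resnum": p.center[1],
                "summed_prob": p.summed_probability,
                "n_members": len(p.members),
                "members": ";".join(f"{m[0]}:{m[1]}" for m in p.members),
            }
            for p in patches
        ]
    ).to_csv(path, sep="\t", index=False)
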