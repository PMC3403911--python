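"""Static visualization and coordinate export.

Plots follow the conventions of the sequence-space figures this tool is
built around: active elements as dots, supplementary (projected) elements
as crosses, colors resolved through a user group annotation with
unannotated elements in black, and axis labels carrying each component's
share of the total variance.  Every plot also writes a CSV of exactly the
plotted coordinates next to the image, so figures stay testable.

``write_mmds_pdb`` exports the first three components as a PDB file (one
CA pseudo-atom per element, one chain per group) for viewing sequence
spaces in molecular graphics programs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless-safe; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .alignment_io import DEFAULT_COLOR, GroupAnnotation
from .errors import ChainExhaustionError, EmptyGroupError, InvalidAxisError
from .mds_core import MdsSpace, ProjectionResult, variance_summary

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

#: Target magnitude for PDB coordinates: factor scores are rescaled so the
#: largest absolute coordinate is 99, comfortably inside the 8.3 field.
_PDB_TARGET = 99.0


def _check_axes(space: MdsSpace, axes: tuple[int, ...]) -> None:
    if len(set(axes)) != len(axes):
        raise InvalidAxisError(f"duplicate component indices in {axes}")
    for a in axes:
        if not 1 <= a <= space.n_components:
            raise InvalidAxisError(
                f"component {a} out of range 1..{space.n_components}"
            )


def _axis_label(space: MdsSpace, component: int) -> str:
    share = variance_summary(space)["pct_variance"].iloc[component - 1]
    return f"PC{component} ({share:.1f}%)"


def _collect(
    space: MdsSpace,
    proj: ProjectionResult | None,
    groups: GroupAnnotation | None,
    axes: tuple[int, ...],
) -> pd.DataFrame:
    cols = [a - 1 for a in axes]
    frames = []
    for ids, scores, role in (
        (space.ids, space.factor_scores, "active"),
        (proj.ids if proj else [], proj.factor_scores if proj is not None else None, "supplementary"),
    ):
        if not ids:
            continue
        df = pd.DataFrame(
            scores[:, cols], columns=[f"PC{a}" for a in axes]
        )
        df.insert(0, "id", list(ids))
        df["role"] = role
        if groups is not None:
            df["group"] = [groups.group_of(i) for i in ids]
            df["color"] = [groups.color_of(i) for i in ids]
        else:
            df["group"] = "all"
            df["color"] = DEFAULT_COLOR
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _sidecar(out: Path, data: pd.DataFrame) -> None:
    data.to_csv(out.with_suffix(out.suffix + ".csv"), index=False)


def plot_2d(
    space: MdsSpace,
    proj: ProjectionResult | None = None,
    groups: GroupAnnotation | None = None,
    axes: tuple[int, int] = (1, 2),
    out: str | Path = "mds_2d.png",
) -> Path:
    """Scatter of two components; supplementary elements overlaid as crosses."""
    _check_axes(space, axes)
    out = Path(out)
    data = _collect(space, proj, groups, axes)
    fig, ax = plt.subplots(figsize=(7, 6))
    for role, marker in (("active", "o"), ("supplementary", "x")):
        sub = data[data["role"] == role]
        if len(sub):
            ax.scatter(
                sub[f"PC{axes[0]}"], sub[f"PC{axes[1]}"],
                c=list(sub["color"]), marker=marker, s=22,
                label=role if proj is not None else None,
            )
    ax.set_xlabel(_axis_label(space, axes[0]))
    ax.set_ylabel(_axis_label(space, axes[1]))
    ax.axhline(0, lw=0.3, color="grey")
    ax.axvline(0, lw=0.3, color="grey")
    if proj is not None:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _sidecar(out, data)
    return out


def plot_3d(
    space: MdsSpace,
    proj: ProjectionResult | None = None,
    groups: GroupAnnotation | None = None,
    axes: tuple[int, int, int] = (1, 2, 3),
    out: str | Path = "mds_3d.png",
) -> Path:
    """Static perspective rendering of three components."""
    _check_axes(space, axes)
    out = Path(out)
    data = _collect(space, proj, groups, axes)
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for role, marker in (("active", "o"), ("supplementary", "x")):
        sub = data[data["role"] == role]
        if len(sub):
            ax.scatter(
                sub[f"PC{axes[0]}"], sub[f"PC{axes[1]}"], sub[f"PC{axes[2]}"],
                c=list(sub["color"]), marker=marker, s=18,
            )
    ax.set_xlabel(_axis_label(space, axes[0]))
    ax.set_ylabel(_axis_label(space, axes[1]))
    ax.set_zlabel(_axis_label(space, axes[2]))
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _sidecar(out, data)
    return out


def plot_barycenters(
    space: MdsSpace,
    groups: GroupAnnotation,
    axes: tuple[int, int] = (1, 2),
    out: str | Path = "mds_barycenters.png",
) -> Path:
    """One symbol per group at the unweighted mean of its members' scores."""
    _check_axes(space, axes)
    out = Path(out)
    cols = [a - 1 for a in axes]
    rows = []
    for group in groups.groups:
        member_idx = [
            k for k, sid in enumerate(space.ids) if groups.group_of(sid) == group
        ]
        if not member_idx:
            continue
        center = space.factor_scores[np.asarray(member_idx)][:, cols].mean(axis=0)
        color = next(
            groups.color_of(sid) for sid in space.ids if groups.group_of(sid) == group
        )
        rows.append({
            "group": group, "n_members": len(member_idx),
            f"PC{axes[0]}": center[0], f"PC{axes[1]}": center[1], "color": color,
        })
    if not rows:
        raise EmptyGroupError("no annotated elements found in the space")
    data = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(
        data[f"PC{axes[0]}"], data[f"PC{axes[1]}"],
        c=list(data["color"]), marker="D", s=70,
    )
    for _, row in data.iterrows():
        ax.annotate(row["group"], (row[f"PC{axes[0]}"], row[f"PC{axes[1]}"]),
                    textcoords="offset points", xytext=(5, 5), fontsize=8)
    ax.set_xlabel(_axis_label(space, axes[0]))
    ax.set_ylabel(_axis_label(space, axes[1]))
    ax.axhline(0, lw=0.3, color="grey")
    ax.axvline(0, lw=0.3, color="grey")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    _sidecar(out, data)
    return out


def write_mmds_pdb(
    space: MdsSpace,
    proj: ProjectionResult | None = None,
    groups: GroupAnnotation | None = None,
    out: str | Path = "mds_space.pdb",
) -> Path:
    """Export PC1..PC3 as CA pseudo-atoms, one chain per group.

    Coordinates are multiplied by a common scale factor (recorded in a
    REMARK 250 line) so they fill the fixed-width PDB coordinate fields;
    spaces with fewer than three retained components are zero-padded.
    Supplementary elements, when no group annotation is given, go to a
    separate chain from the active elements.
    """
    out = Path(out)
    blocks: list[tuple[str, np.ndarray, str]] = [("active", space.factor_scores, "A")]
    if proj is not None:
        blocks.append(("supplementary", proj.factor_scores, "B"))

    all_ids: list[str] = []
    coords_list = []
    roles: list[str] = []
    for role, scores, _ in blocks:
        k = scores.shape[0]
        xyz = np.zeros((k, 3))
        m = min(3, scores.shape[1])
        xyz[:, :m] = scores[:, :m]
        coords_list.append(xyz)
        ids = space.ids if role == "active" else proj.ids
        all_ids.extend(ids)
        roles.extend([role] * k)
    coords = np.vstack(coords_list)

    if groups is not None:
        group_order: list[str] = []
        for sid in all_ids:
            g = groups.group_of(sid)
            if g not in group_order:
                group_order.append(g)
        if len(group_order) > len(_CHAIN_IDS):
            raise ChainExhaustionError(
                f"{len(group_order)} groups exceed the "
                f"{len(_CHAIN_IDS)} available PDB chain identifiers"
            )
        chain_of = {g: _CHAIN_IDS[i] for i, g in enumerate(group_order)}
        chains = [chain_of[groups.group_of(sid)] for sid in all_ids]
    else:
        chains = ["A" if role == "active" else "B" for role in roles]

    max_abs = np.abs(coords).max()
    scale = _PDB_TARGET / max_abs if max_abs > 0 else 1.0
    scaled = coords * scale

    lines = [
        "REMARK 250 SEQUENCE SPACE COORDINATES (PC1-PC3) FROM METRIC MDS",
        f"REMARK 250 SCALE FACTOR {scale:.6e} (DIVIDE COORDINATES TO RECOVER)",
    ]
    for serial, (sid, (x, y, z), chain) in enumerate(
        zip(all_ids, scaled, chains), start=1
    ):
        lines.append(
            f"ATOM  {serial:>5d}  CA  GLY {chain}{serial % 10000:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    out.write_text("\n".join(lines) + "\n")
    return out


def read_mmds_pdb(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Parse a file written by :func:`write_mmds_pdb`.

    Returns unscaled coordinates, per-atom chain ids, and the scale factor.
    """
    scale = 1.0
    coords = []
    chains = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("REMARK 250 SCALE FACTOR"):
            scale = float(line.split()[4])
        elif line.startswith("ATOM"):
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
            chains.append(line[21])
    return np.asarray(coords) / scale, chains, scale
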