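"""Local accuracy estimates (LAE) from prediction files and their
correlation with local resolution.

Prediction formats carry per-residue accuracy estimates in the B-factor
column: pLDDT on a 0-1 or 0-100 scale (higher is better), or a positional
error in Å (lower is better).  Because the direction differs between
conventions, the correlation against local resolution is reported as an
absolute Pearson coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AtomicModel, ResidueTrack
from .ensemble import pearson

__all__ = ["LAETrack", "extract_lae", "lae_locres_pcc", "LAEAbsentError"]


class LAEAbsentError(ValueError):
    """No accuracy estimates present (e.g. RNA predictions without pLDDT).

    Distinguishable from other failures so pipelines can report the model
    as not-assessable rather than scoring it 0.
    """


@dataclass
class LAETrack:
    """A per-residue accuracy-estimate track with its scale convention."""

    track: ResidueTrack
    scale: str  # unit | percent | error_angstrom
    direction: str  # higher_better | lower_better


def extract_lae(model: AtomicModel, scale: str | None = None) -> LAETrack:
    """Per-residue accuracy estimate: the representative atom's B-field.

    The scale is auto-detected from the value range unless given:
    max <= 1.001 -> unit pLDDT-like score; max <= 100.5 -> percent
    (converted to unit scale); anything larger -> positional error in Å
    (lower is better).  An all-zero B-field column raises
    :class:`LAEAbsentError`.
    """
    values = []
    for res in model.residues():
        rep = res.representative_atom
        if rep is not None:
            values.append((res.key, float(rep.bfield)))
    if not values or all(v == 0.0 for _, v in values):
        raise LAEAbsentError(f"model {model.model_id!r}: no accuracy estimates present")

    vmax = max(v for _, v in values)
    if scale is None:
        scale = "unit" if vmax <= 1.001 else ("percent" if vmax <= 100.5 else "error_angstrom")
    if scale not in ("unit", "percent", "error_angstrom"):
        raise ValueError(f"unknown LAE scale {scale!r}")

    track = ResidueTrack(name="LAE", units="score" if scale != "error_angstrom" else "angstrom")
    for key, v in values:
        track[key] = v / 100.0 if scale == "percent" else v
    return LAETrack(
        track=track,
        scale="unit" if scale == "percent" else scale,
        direction="lower_better" if scale == "error_angstrom" else "higher_better",
    )


def lae_locres_pcc(lae: LAETrack, locres_track: ResidueTrack) -> tuple[float | None, int]:
    """|Pearson r| between accuracy estimates and local resolution.

    The absolute value makes the comparison direction-agnostic: a good
    higher-is-better estimate anti-correlates with resolution values
    (larger = worse), a good error estimate correlates positively, and
    both end up near |r| = 1.
    """
    return pearson(lae.track, locres_track, absolute=True)
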