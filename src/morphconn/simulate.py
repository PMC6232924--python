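"""Synthetic cohorts of cortical-attribute tables with planted structure.

The generator emulates the shape of a FreeSurfer-derived cohort: per
subject, one mean value per ROI for each of several cortical attributes
whose template scales differ by orders of magnitude (curvatures in 1/mm
around 0.1, thickness and sulcal depth in mm around 1.5-2.5).  Structure is
planted at three levels:

* a diagnostic-group effect — each ROI x attribute mean is shifted between
  the two groups by ``separation`` noise SDs (a random signed pattern,
  since the absolute-difference networks are invariant to a shift common to
  all ROIs);
* optional within-group subgroups, shifted analogously by
  ``subgroup_separation``;
* measurement noise, iid Gaussian with SD ``noise_sd`` for every
  ROI x attribute cell (Student-t with 3 degrees of freedom under
  ``heavy_tailed``).

Everything is drawn from one seeded generator, so cohorts are bit-identical
given the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AttributeTable, Cohort

# name, typical ROI mean, between-ROI spread of the template
ATTRIBUTE_PRESETS = [
    ("max_principal_curvature", 0.13, 0.030),
    ("mean_cortical_thickness", 2.60, 0.350),
    ("mean_sulcal_depth", 1.60, 0.500),
    ("mean_average_curvature", 0.03, 0.015),
]

GROUP_LABELS = ("ASD", "NC")


def _attribute_presets(n_v: int):
    presets = list(ATTRIBUTE_PRESETS)
    for v in range(len(presets), n_v):
        presets.append((f"attribute_{v}", 1.0, 0.30))
    return presets[:n_v]


@dataclass(frozen=True)
class SimSpec:
    """Conditions of one synthetic cohort draw."""

    n_per_group: tuple[int, int] = (30, 30)
    n_r: int = 12
    n_v: int = 4
    separation: float = 0.0
    n_subgroups: int = 1
    subgroup_separation: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    hemisphere: str = "left"
    heavy_tailed: bool = False

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1 or self.n_r < 2 or self.n_v < 2:
            raise ValueError("counts must satisfy n_per_group >= 1, n_r >= 2, n_v >= 2")
        if self.n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.separation < 0 or self.subgroup_separation < 0:
            raise ValueError("separations must be nonnegative")


def _noise(rng: np.random.Generator, shape, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        df = 3.0
        return rng.standard_t(df, size=shape) * sd / np.sqrt(df / (df - 2.0))
    return rng.normal(0.0, sd, size=shape)


def _base_template(rng: np.random.Generator, n_r: int, n_v: int) -> tuple:
    presets = _attribute_presets(n_v)
    attr_names = [p[0] for p in presets]
    loc = np.array([p[1] for p in presets])
    spread = np.array([p[2] for p in presets])
    base = loc[None, :] + rng.normal(0.0, 1.0, (n_r, n_v)) * spread[None, :]
    return base, attr_names


def _assemble(spec: SimSpec, rng: np.random.Generator, attr_names, templates,
              subgroup_of) -> Cohort:
    """templates: (group, subgroup) -> n_r x n_v mean matrix."""
    roi_names = [f"roi_{r:02d}" for r in range(spec.n_r)]
    subjects = []
    sid = 0
    for g, (label, n_g) in enumerate(zip(GROUP_LABELS, spec.n_per_group)):
        for i in range(n_g):
            sg = subgroup_of(g, i)
            values = templates[(g, sg)] + _noise(
                rng, (spec.n_r, spec.n_v), spec.noise_sd, spec.heavy_tailed)
            subjects.append(AttributeTable(
                subject_id=f"sub-{sid:04d}", hemisphere=spec.hemisphere,
                label=label, values=values, roi_names=list(roi_names),
                attribute_names=list(attr_names), subgroup=sg,
            ))
            sid += 1
    return Cohort(subjects)


def generate_cohort(spec: SimSpec) -> Cohort:
    """Draw one cohort with planted group and subgroup structure."""
    rng = np.random.default_rng(spec.seed)
    base, attr_names = _base_template(rng, spec.n_r, spec.n_v)

    # group 0 sits at the base template; group 1 is shifted by a random
    # per-cell pattern of size `separation` noise SDs
    group_templates = [
        base,
        base + spec.separation * spec.noise_sd
        * rng.normal(0.0, 1.0, (spec.n_r, spec.n_v)),
    ]
    templates = {}
    for g in range(2):
        for sg in range(spec.n_subgroups):
            offset = (spec.subgroup_separation * spec.noise_sd
                      * rng.normal(0.0, 1.0, (spec.n_r, spec.n_v))
                      if spec.n_subgroups > 1 else 0.0)
            templates[(g, sg)] = group_templates[g] + offset
    return _assemble(spec, rng, attr_names, templates,
                     lambda g, i: i % spec.n_subgroups)


def plant_discriminative_edge(spec: SimSpec, roi_pair: tuple[int, int],
                              attribute: int, effect: float) -> Cohort:
    """Cohort whose only group difference is one ROI pair's attribute gap.

    Both groups share one template (no random group shift, no subgroups),
    drawn exactly as in :func:`generate_cohort`.  On the chosen attribute
    the two planted ROIs are repositioned symmetrically about their midpoint
    with a gap far wider than the effect and the noise, so the (i, j)
    absolute difference is sign-stable; group 1's ROI *i* is then raised and
    ROI *j* lowered by ``effect / 2`` noise SDs each, moving the (i, j)
    difference by the full ``effect`` while any other edge incident to *i*
    or *j* moves by only half of it (in expectation) and non-incident edges
    not at all.
    """
    i, j = roi_pair
    if not (0 <= i < spec.n_r and 0 <= j < spec.n_r and i != j):
        raise IndexError(f"roi_pair {roi_pair} out of range for n_r={spec.n_r}")
    if not 0 <= attribute < spec.n_v:
        raise IndexError(f"attribute index {attribute} out of range")

    rng = np.random.default_rng(spec.seed)
    base, attr_names = _base_template(rng, spec.n_r, spec.n_v)

    gap = (abs(effect) + 8.0) * spec.noise_sd
    mid = (base[i, attribute] + base[j, attribute]) / 2.0
    base[i, attribute] = mid + gap / 2.0
    base[j, attribute] = mid - gap / 2.0

    shift = np.zeros((spec.n_r, spec.n_v))
    shift[i, attribute] = +0.5 * effect * spec.noise_sd
    shift[j, attribute] = -0.5 * effect * spec.noise_sd
    templates = {(0, 0): base, (1, 0): base + shift}
    return _assemble(spec, rng, attr_names, templates, lambda g, k: 0)
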