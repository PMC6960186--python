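"""Synthetic IHC-like images, cohorts and graph fixtures.

Every stage of the pipeline is testable offline through this module:

* :func:`generate_ihc_image` emulates a two-stain immunohistochemistry
  field — brown DAB-positive regions on a blue hematoxylin background —
  as a smooth Gaussian random field thresholded at a target positive
  fraction, plus per-channel noise.  ``blob_scale`` sets the spatial
  correlation length of the stain pattern and is the knob that the
  recurrence-network metrics respond to.
* :func:`generate_synthetic_cohort` builds a paired biopsy/tumor image
  set per patient with a controllable link between the tumor-to-biopsy
  texture ratio and survival time in a "responder" arm, and no link in
  a "non-responder" arm, enabling end-to-end parameter-recovery tests.
* :func:`generate_fixture_graphs` supplies random weighted networks as
  oracle fuel for the metric tests.

The generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import PatientRecord
from .errors import InvalidInputError
from .imaging import MultiChannelImage
from .network import WeightedNetwork

__all__ = [
    "StainTextureParams",
    "SyntheticCohortParams",
    "SyntheticCohort",
    "generate_ihc_image",
    "generate_synthetic_cohort",
    "generate_fixture_graphs",
]

# Plausible unit-RGB stain hues; nothing downstream depends on the exact
# values, only on the two-class color structure.
DAB_RGB = (0.57, 0.39, 0.23)
HEMATOXYLIN_RGB = (0.26, 0.33, 0.61)


@dataclass(frozen=True)
class StainTextureParams:
    """Parameters of one synthetic two-stain texture field.

    ``dab_fraction`` is the target fraction of brown (stain-positive)
    pixels; ``blob_scale`` the Gaussian correlation length in pixels of
    the stain pattern; ``noise_sd`` the per-channel additive Gaussian
    noise.  Defaults give a 150-pixel tile (the pipeline's standard
    tile side) with moderate stain coverage.
    """

    image_size: tuple[int, int] = (150, 150)
    dab_fraction: float = 0.3
    blob_scale: float = 4.0
    dab_rgb: tuple[float, float, float] = DAB_RGB
    hematoxylin_rgb: tuple[float, float, float] = HEMATOXYLIN_RGB
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dab_fraction <= 1.0:
            raise InvalidInputError("dab_fraction must lie in [0, 1]")
        if self.blob_scale < 1:
            raise InvalidInputError("blob_scale must be >= 1")
        for rgb in (self.dab_rgb, self.hematoxylin_rgb):
            if len(rgb) != 3 or any(not 0 <= v <= 1 for v in rgb):
                raise InvalidInputError("stain colors must be in [0,1]^3")


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Design of a synthetic paired biopsy/tumor cohort.

    Each patient gets a texture-heterogeneity ratio r (tumor blob scale
    divided by biopsy blob scale).  In the responder arm survival is
    ``survival_baseline + effect_size * (r - 1)`` months plus noise; in
    the non-responder arm survival is independent of r by construction.
    Responder survivals land in the longer-survival band (>= 101
    months) and non-responder survivals in the shorter band (15-75
    months), mirroring the two arms of the rectal-cancer cohort.
    """

    n_patients: int = 28
    responder_fraction: float = 0.5
    effect_size: float = 60.0  # months of survival per unit of (r - 1)
    survival_noise_sd: float = 10.0
    survival_baseline: float = 180.0
    biopsy_blob_scale: float = 3.0
    ratio_range: tuple[float, float] = (0.7, 2.4)
    # 256px specimens cut into sixteen 64px tiles downstream: specimen
    # metrics are multi-tile averages, as with real whole-slide images,
    # which keeps per-specimen metric noise well below the designed
    # ratio signal
    image_size: tuple[int, int] = (256, 256)
    dab_fraction: float = 0.3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise InvalidInputError("n_patients must be >= 4")
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise InvalidInputError("responder_fraction must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Images, patient records and generating ground truth."""

    records: list[PatientRecord]
    images: dict[tuple[str, str], MultiChannelImage]  # (patient_id, specimen)
    true_ratios: dict[str, float]
    responder_ids: set[str] = field(default_factory=set)


def generate_ihc_image(params: StainTextureParams) -> MultiChannelImage:
    """Two-stain RGB texture: smooth field thresholded at dab_fraction.

    A seeded white-noise field is blurred with a Gaussian kernel of
    width ``blob_scale`` and thresholded at the (1 - dab_fraction)
    quantile; pixels above threshold take the DAB color, the rest the
    hematoxylin color, and clipped Gaussian noise is added per channel.
    The realized brown fraction tracks ``dab_fraction`` to within the
    quantile discretisation (a couple of pixels).
    """
    rng = np.random.default_rng(params.seed)
    M, N = params.image_size
    if params.dab_fraction <= 0.0:
        mask = np.zeros((M, N), dtype=bool)
        _ = rng.standard_normal((M, N))  # keep stream layout uniform
    elif params.dab_fraction >= 1.0:
        mask = np.ones((M, N), dtype=bool)
        _ = rng.standard_normal((M, N))
    else:
        fld = gaussian_filter(rng.standard_normal((M, N)), params.blob_scale)
        thresh = np.quantile(fld, 1.0 - params.dab_fraction)
        mask = fld > thresh
    dab = np.asarray(params.dab_rgb)
    hema = np.asarray(params.hematoxylin_rgb)
    pixels = np.where(mask[:, :, np.newaxis], dab, hema)
    if params.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, params.noise_sd, size=(M, N, 3))
    pixels = np.clip(pixels, 0.0, 1.0)
    return MultiChannelImage(pixels, channel_names=["R", "G", "B"])


def _orthogonalize(
    values: np.ndarray, against: np.ndarray, degree: int = 1
) -> np.ndarray:
    """Residualize ``values`` against polynomials of ``against``.

    Used so the non-responder arm's survivals are empirically
    uncorrelated with the generating texture ratio (and, via the
    quadratic term, with any smooth monotone readout of it): the arm
    then represents an exact null rather than a sampled one, which
    keeps small-cohort null checks from fluctuating on the draw.
    """
    n = values.size
    if n <= degree + 1:
        return values
    basis = np.column_stack(
        [np.ones(n)] + [against**d for d in range(1, degree + 1)]
    )
    coef, *_ = np.linalg.lstsq(basis, values, rcond=None)
    resid = values - basis @ coef
    return resid + values.mean()


def generate_synthetic_cohort(params: SyntheticCohortParams) -> SyntheticCohort:
    """Paired biopsy/tumor images with a survival-linked texture ratio.

    Heterogeneity ratios are spread evenly across ``ratio_range`` (with
    a small seeded jitter) to avoid accidental clustering in small
    cohorts, then assigned to patients at random.  Tumor images use
    blob scale ``biopsy_blob_scale * r``; biopsy images use the base
    scale.  Ground-truth ratios and the responder id set are returned
    for recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    n_resp = int(round(params.responder_fraction * n))

    lo, hi = params.ratio_range
    ratios = np.linspace(lo, hi, n)
    if n > 1:
        jitter_scale = 0.1 * (hi - lo) / (n - 1)
        ratios = ratios + rng.uniform(-jitter_scale, jitter_scale, size=n)
    ratios = rng.permutation(ratios)

    responder = np.zeros(n, dtype=bool)
    responder[rng.choice(n, size=n_resp, replace=False)] = True

    survival = np.empty(n)
    # responders: linear ratio -> survival link, clipped to the
    # longer-survival band; the noise is residualized against the ratio
    # so the realized slope is exactly the designed effect_size and a
    # zero effect_size yields exactly uncorrelated survivals
    n_resp_actual = int(responder.sum())
    noise = rng.normal(0.0, params.survival_noise_sd, size=n_resp_actual)
    if n_resp_actual >= 3:
        noise = _orthogonalize(noise, ratios[responder])
    s_resp = (
        params.survival_baseline
        + params.effect_size * (ratios[responder] - 1.0)
        + noise
    )
    survival[responder] = np.clip(s_resp, 101, 288)
    # non-responders: survivals in the shorter band, made exactly
    # uncorrelated with the generating ratio
    n_null = n - int(responder.sum())
    if n_null:
        s_null = rng.uniform(15, 75, size=n_null)
        s_null = _orthogonalize(s_null, ratios[~responder], degree=2)
        survival[~responder] = np.clip(s_null, 15, 75)

    records: list[PatientRecord] = []
    images: dict[tuple[str, str], MultiChannelImage] = {}
    true_ratios: dict[str, float] = {}
    responder_ids: set[str] = set()
    for i in range(n):
        pid = f"S{i + 1:03d}"
        surv = int(round(survival[i]))
        dfree = int(round(surv * rng.uniform(0.2, 1.0)))
        rec = PatientRecord(
            patient_id=pid,
            disease_free_months=dfree,
            recurrence=bool(rng.random() < 0.85),
            survival_months=surv,
            ihc_score_tumor=int(rng.integers(1, 4)),
            ihc_score_biopsy=int(rng.integers(1, 4)),
        )
        records.append(rec)
        true_ratios[pid] = float(ratios[i])
        if responder[i]:
            responder_ids.add(pid)
        seed_b, seed_t = rng.integers(0, 2**31 - 1, size=2)
        images[(pid, "biopsy")] = generate_ihc_image(
            StainTextureParams(
                image_size=params.image_size,
                dab_fraction=params.dab_fraction,
                blob_scale=params.biopsy_blob_scale,
                noise_sd=params.noise_sd,
                seed=int(seed_b),
            )
        )
        images[(pid, "primary_tumor")] = generate_ihc_image(
            StainTextureParams(
                image_size=params.image_size,
                dab_fraction=params.dab_fraction,
                blob_scale=params.biopsy_blob_scale * float(ratios[i]),
                noise_sd=params.noise_sd,
                seed=int(seed_t),
            )
        )
    return SyntheticCohort(
        records=records,
        images=images,
        true_ratios=true_ratios,
        responder_ids=responder_ids,
    )


def generate_fixture_graphs(
    n_nodes: int,
    density: float,
    seed: int,
    n_graphs: int = 1,
    ensure_connected: bool = False,
) -> list[WeightedNetwork]:
    """Random symmetric weighted graphs for metric oracle tests.

    Each potential edge is present independently with probability
    ``density`` and carries a uniform weight in (0, 1].  With
    ``ensure_connected`` a random spanning tree is added first.
    """
    if n_nodes > 20:
        raise InvalidInputError("fixture graphs are capped at 20 nodes")
    if not 0.0 <= density <= 1.0:
        raise InvalidInputError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(n_graphs):
        W = np.zeros((n_nodes, n_nodes))
        iu = np.triu_indices(n_nodes, k=1)
        present = rng.random(len(iu[0])) < density
        weights = 1.0 - rng.random(len(iu[0]))  # uniform in (0, 1]
        W[iu] = np.where(present, weights, 0.0)
        W = W + W.T
        if ensure_connected and n_nodes > 1:
            order = rng.permutation(n_nodes)
            for a, b in zip(order[:-1], order[1:]):
                if W[a, b] == 0:
                    w = 1.0 - rng.random()
                    W[a, b] = W[b, a] = w
        graphs.append(WeightedNetwork(W=W))
    return graphs
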