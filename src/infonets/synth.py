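"""Synthetic-study generation: meshes, groups, planted signal, stimuli.

A synthetic study emulates the data a two-group surface-searchlight RSA
study consumes: per-subject item x node pattern-estimate arrays on a
standard mesh, item category labels, and grayscale stimulus images.  Signal
is planted region-by-region so every pipeline stage can be verified by
parameter recovery:

* ``expert_category`` patches: subjects of the expert group share a pattern
  prototype whose item covariance follows the mechanical-category model, so
  their local DMs converge on each other and on the category DM; the novice
  group receives pure noise there.
* ``both_visual`` patches: subjects of *both* groups share a prototype
  following the HMAX-C1 visual model DM of the generated stimulus images.
* ``novice_only`` patches: the novice group shares an arbitrary non-model
  prototype (convergence without category information).
* everywhere else: independent Gaussian noise.

A subject's pattern at node v is ``sqrt(snr) * G[:, v] + noise_sd * eps``
where ``G`` is the patch's shared prototype field (item covariance =
``model_weight`` x target similarity + ``1 - model_weight`` x a
patch-specific random similarity) and ``eps`` is iid standard normal.  All
quantities are in arbitrary beta-like units; there is no claim of
physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .exceptions import ConfigError, InvalidParameterError
from .hmax import StimulusImage, default_gabor_bank, visual_model_dm
from .mesh import WholeBrainSurface, build_whole_brain_surface
from .rsa import CategoryLabels, ModelDM, category_model_dm

__all__ = [
    "PlantedRegionSpec",
    "StudyConfig",
    "SyntheticStudy",
    "GroundTruth",
    "generate_stimulus_images",
    "planted_dm_prototype",
    "DMPrototype",
    "simulate_study",
]

ROLES = ("expert_category", "both_visual", "novice_only")

# Role patch centers: unit directions, one patch per hemisphere per role,
# mutually ~120 degrees apart so patches plus searchlight dilation stay
# disjoint on the L=8 test mesh.
_ROLE_DIRECTIONS = {
    "expert_category": np.array([1.0, 0.0, 0.0]),
    "both_visual": np.array([-0.5, np.sqrt(3) / 2, 0.0]),
    "novice_only": np.array([-0.5, -np.sqrt(3) / 2, 0.0]),
}


@dataclass(frozen=True)
class PlantedRegionSpec:
    """One planted patch: a k-ring ball on one hemisphere."""

    name: str
    role: str
    hemisphere: str
    center_direction: tuple
    patch_rings: int


@dataclass
class StudyConfig:
    """Generator configuration; defaults are the reference study conditions.

    Group sizes 16 (expert) and 15 (novice), 24 items in three categories of
    8, and a searchlight of 2 rings; ``mesh_divisions=8`` is the test-scale
    mesh (1,284 whole-brain nodes), ``32`` the full-scale standard mesh.
    """

    seed: int = 0
    mesh_divisions: int = 8
    n_items: int = 24
    category_sizes: tuple = (8, 8, 8)
    group_sizes: tuple = (16, 15)
    snr: float = 1.0
    searchlight_rings: int = 2
    patch_rings: int = 5
    support_erosion: int = 1
    model_weight: float = 0.75
    n_spatial_modes: int = 6
    noise_sd: float = 1.0
    image_size: int = 128
    planted_regions: tuple | None = None
    category_names: tuple = ("cantilever", "truss", "vertical_load")

    def __post_init__(self) -> None:
        if sum(self.category_sizes) != self.n_items:
            raise ConfigError(
                f"category sizes {self.category_sizes} do not sum to {self.n_items} items"
            )
        if len(self.category_sizes) != len(self.category_names):
            raise ConfigError("one category name per category size is required")
        if self.snr < 0:
            raise ConfigError("snr must be non-negative")
        if min(self.group_sizes) < 2:
            raise ConfigError("each group needs at least 2 subjects")

    def default_planted_regions(self) -> tuple:
        specs = []
        for role in ROLES:
            d = _ROLE_DIRECTIONS[role]
            for hemi in ("left", "right"):
                specs.append(
                    PlantedRegionSpec(
                        name=f"{role}_{hemi}",
                        role=role,
                        hemisphere=hemi,
                        center_direction=tuple(d),
                        patch_rings=self.patch_rings,
                    )
                )
        return tuple(specs)


@dataclass
class GroundTruth:
    """Planted region map and planted model per region (for scoring only)."""

    role_nodes: dict            # role -> sorted global node index array
    patches: list               # (spec, nodes array) per patch
    planted_k: dict             # role -> number of planted prototypes
    prototype_targets: dict     # patch name -> target model kind string


@dataclass
class SyntheticStudy:
    config: StudyConfig
    mesh: WholeBrainSurface
    subject_ids: tuple
    groups: dict                # subject_id -> "expert" | "novice"
    betas: dict                 # subject_id -> (n_items, n_nodes) array
    labels: CategoryLabels
    images: list
    category_model: ModelDM
    visual_model: ModelDM
    ground_truth: GroundTruth

    def group_subjects(self, group: str) -> list:
        return [s for s in self.subject_ids if self.groups[s] == group]


# --------------------------------------------------------------------------
# stimulus images
# --------------------------------------------------------------------------

def _draw_cantilever(draw: ImageDraw.ImageDraw, rng, size: int) -> None:
    # anchored horizontal beam: wall at left, beam projecting right, brace
    wall_x = int(size * rng.uniform(0.12, 0.25))
    beam_y = int(size * rng.uniform(0.35, 0.6))
    beam_len = int(size * rng.uniform(0.45, 0.7))
    w = int(rng.integers(2, 4))
    draw.line([(wall_x, int(size * 0.1)), (wall_x, int(size * 0.9))], fill=0, width=w + 1)
    draw.line([(wall_x, beam_y), (wall_x + beam_len, beam_y)], fill=0, width=w)
    brace_drop = int(size * rng.uniform(0.15, 0.3))
    draw.line([(wall_x, beam_y + brace_drop), (wall_x + beam_len // 2, beam_y)], fill=0, width=w)
    if rng.random() < 0.5:  # tip load marker
        tip = wall_x + beam_len
        draw.line([(tip, beam_y), (tip, beam_y + int(size * 0.12))], fill=0, width=w)


def _draw_truss(draw: ImageDraw.ImageDraw, rng, size: int) -> None:
    # triangulated span between two chords
    x0 = int(size * rng.uniform(0.08, 0.2))
    x1 = int(size * rng.uniform(0.8, 0.92))
    top = int(size * rng.uniform(0.3, 0.42))
    bot = top + int(size * rng.uniform(0.18, 0.3))
    n_panels = int(rng.integers(3, 6))
    w = int(rng.integers(1, 3))
    xs = np.linspace(x0, x1, n_panels + 1).astype(int)
    draw.line([(x0, top), (x1, top)], fill=0, width=w)
    draw.line([(x0, bot), (x1, bot)], fill=0, width=w)
    for i in range(n_panels):
        draw.line([(xs[i], bot), (xs[i], top)], fill=0, width=w)
        if i % 2 == 0:
            draw.line([(xs[i], bot), (xs[i + 1], top)], fill=0, width=w)
        else:
            draw.line([(xs[i], top), (xs[i + 1], bot)], fill=0, width=w)
    draw.line([(x1, bot), (x1, top)], fill=0, width=w)


def _draw_vertical_load(draw: ImageDraw.ImageDraw, rng, size: int) -> None:
    # column under a mass block, on a ground line
    col_x = int(size * rng.uniform(0.35, 0.65))
    ground_y = int(size * rng.uniform(0.78, 0.9))
    col_top = int(size * rng.uniform(0.3, 0.45))
    w = int(rng.integers(2, 4))
    draw.line([(int(size * 0.1), ground_y), (int(size * 0.9), ground_y)], fill=0, width=w)
    draw.line([(col_x, ground_y), (col_x, col_top)], fill=0, width=w)
    bw = int(size * rng.uniform(0.12, 0.22))
    bh = int(size * rng.uniform(0.08, 0.16))
    draw.rectangle([col_x - bw, col_top - bh, col_x + bw, col_top], outline=0, width=w)


_DRAWERS = {
    "cantilever": _draw_cantilever,
    "truss": _draw_truss,
    "vertical_load": _draw_vertical_load,
}


def generate_stimulus_images(
    labels: CategoryLabels, seed: int, size: int = 128
) -> list[StimulusImage]:
    """Render synthetic line-drawing structures, one per labeled item.

    Each category has a characteristic geometry (cantilever: anchored
    horizontal beam; truss: triangulated span; vertical load: column under a
    mass), but viewpoint, scale, line weight, background texture and
    distractor strokes are randomized per item so that low-level visual
    similarity does not trivially encode the category.  Deterministic for a
    fixed seed.  These are synthetic stand-ins, not any real stimulus set.
    """
    ss = np.random.SeedSequence([int(seed), 0x57A7])
    images = []
    for item_id, cat, child in zip(
        labels.item_ids, labels.categories, ss.spawn(len(labels.item_ids))
    ):
        rng = np.random.default_rng(child)
        canvas = int(size * 1.4)
        img = Image.new("L", (canvas, canvas), color=255)
        draw = ImageDraw.Draw(img)
        off = (canvas - size) // 2
        # draw the structure into the central size x size window
        sub = Image.new("L", (size, size), color=255)
        sdraw = ImageDraw.Draw(sub)
        _DRAWERS[cat](sdraw, rng, size)
        # distractor strokes decorrelate visual similarity from category
        for _ in range(int(rng.integers(2, 6))):
            pts = rng.uniform(0, size, size=4).astype(int)
            sdraw.line(
                [tuple(pts[:2]), tuple(pts[2:])],
                fill=int(rng.integers(0, 140)),
                width=int(rng.integers(1, 3)),
            )
        img.paste(sub, (off, off))
        # full viewpoint randomization: orientation statistics must not
        # trivially encode the structural category
        angle = float(rng.uniform(0, 360))
        img = img.rotate(angle, resample=Image.BILINEAR, fillcolor=255)
        img = img.crop((off, off, off + size, off + size))
        pix = np.asarray(img, dtype=np.float64) / 255.0
        # smooth background gradient + pixel noise
        gy, gx = np.mgrid[0:size, 0:size] / size
        gdir = rng.uniform(-1, 1, size=2)
        pix = pix + 0.1 * (gdir[0] * gx + gdir[1] * gy) + rng.normal(0, 0.02, pix.shape)
        pix = np.clip(pix, 0.0, 1.0)
        images.append(StimulusImage(item_id=item_id, pixels=pix, source="synthetic"))
    return images


# --------------------------------------------------------------------------
# planted prototypes
# --------------------------------------------------------------------------

def _shrink_to_psd(S: np.ndarray, coherence: float, margin: float = 0.05) -> np.ndarray:
    """Shrink a unit-diagonal similarity toward the identity until its
    smallest eigenvalue reaches ``margin``.

    Shrinkage scales the off-diagonal entries by a common factor, so the
    correlation between the result and the original structure is exactly 1;
    unlike an eigenvalue clip it cannot distort the planted geometry.
    """
    lam = float(np.linalg.eigvalsh((S + S.T) / 2).min())
    beta = coherence if lam >= margin else min(coherence, (1.0 - margin) / (1.0 - lam))
    out = beta * S + (1.0 - beta) * np.eye(len(S))
    np.fill_diagonal(out, 1.0)
    return out


def _similarity_from_model(
    model: ModelDM,
    coherence: float = 0.8,
    contrast: float = 0.35,
    base: float = 0.3,
) -> np.ndarray:
    """Target item similarity: an affine map of the model DM, PSD by
    shrinkage so the planted correlation structure is preserved exactly.

    The off-diagonal entries are standardized to a common contrast
    (``sd = contrast`` around ``base``) so that different model DMs are
    planted at the same representational amplitude regardless of their
    native spread; correlation with the model is unaffected (affine map).
    """
    d = model.dm.to_square()
    if d.max() <= 0:
        raise InvalidParameterError("model DM is identically zero")
    n = len(d)
    iu = np.triu_indices(n, k=1)
    s = 1.0 - d[iu] / d.max()
    sd = s.std()
    if sd == 0:
        raise InvalidParameterError("model DM is constant")
    s = base + contrast * (s - s.mean()) / sd
    sim = np.eye(n)
    sim[iu] = s
    sim = sim + sim.T - np.eye(n)
    np.fill_diagonal(sim, 1.0)
    return _shrink_to_psd(sim, coherence)


def _orthogonalized_random_similarity(
    n_items: int,
    rng,
    exclude_condensed: list[np.ndarray] | None = None,
    n_factors: int = 3,
    amplitude: float = 0.4,
) -> np.ndarray:
    """A random similarity whose condensed structure is orthogonal to the
    given model DM vectors (no accidental model correlation)."""
    A = rng.normal(size=(n_items, n_factors))
    S = A @ A.T
    dd = np.sqrt(np.diag(S))
    S = S / np.outer(dd, dd)
    iu = np.triu_indices(n_items, k=1)
    s = S[iu]
    s = s - s.mean()
    for v in exclude_condensed or []:
        v = np.asarray(v, dtype=np.float64)
        v = v - v.mean()
        nv = np.linalg.norm(v)
        if nv > 0:
            s = s - (s @ v / nv**2) * v
    sd = s.std()
    if sd > 0:
        s = s * (amplitude / sd)
    out = np.eye(n_items)
    out[iu] = s
    out = out + out.T - np.eye(n_items)
    np.fill_diagonal(out, 1.0)
    return _shrink_to_psd(out, coherence=1.0)


@dataclass
class DMPrototype:
    """A shared pattern field whose local DMs track a target model DM.

    ``shared`` is ``sqrt(snr) * G`` with ``G[:, f] ~ N(0, S)`` iid over
    features; a subject realization adds unit-variance Gaussian noise, so
    the expected correlation between two items' realized patterns is
    ``snr * S_ij / (snr + 1)`` — monotone in snr, independent at snr 0.
    """

    shared: np.ndarray          # (n_items, n_features)
    snr: float
    target_similarity: np.ndarray

    def realization(self, rng, noise_sd: float = 1.0) -> np.ndarray:
        return self.shared + rng.normal(scale=noise_sd, size=self.shared.shape)


def _similarity_root(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((S + S.T) / 2)
    return V * np.sqrt(np.clip(w, 1e-12, None))


def planted_dm_prototype(
    model: ModelDM,
    snr: float,
    n_features: int = 64,
    seed: int = 0,
    model_weight: float = 1.0,
    rng=None,
    exclude_models: list[ModelDM] | None = None,
) -> DMPrototype:
    """Construct a planted pattern prototype for a target model DM.

    ``model_weight < 1`` mixes in a random prototype-specific similarity
    component (orthogonalized against ``exclude_models`` so it carries no
    accidental model correlation), keeping distinct patches that target the
    same model distinguishable by clustering.
    """
    if snr < 0:
        raise InvalidParameterError("snr must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    S_target = _similarity_from_model(model)
    n_items = len(S_target)
    if model_weight < 1.0:
        exclude = [m.dm.condensed for m in (exclude_models or [model])]
        S_spec = _orthogonalized_random_similarity(n_items, rng, exclude)
        S = model_weight * S_target + (1.0 - model_weight) * S_spec
    else:
        S = S_target
    G = _similarity_root(S) @ rng.normal(size=(n_items, n_features))
    return DMPrototype(shared=np.sqrt(snr) * G, snr=float(snr), target_similarity=S)


def _arbitrary_prototype(
    n_items: int,
    snr: float,
    n_features: int,
    rng,
    exclude_models: list[ModelDM] | None = None,
) -> DMPrototype:
    """Shared structure that follows no model DM (novice-only convergence)."""
    exclude = [m.dm.condensed for m in (exclude_models or [])]
    S = _orthogonalized_random_similarity(n_items, rng, exclude)
    G = _similarity_root(S) @ rng.normal(size=(n_items, n_features))
    return DMPrototype(shared=np.sqrt(snr) * G, snr=float(snr), target_similarity=S)


def _spatial_field(
    S: np.ndarray,
    coords: np.ndarray,
    n_modes: int,
    rng,
    snr: float,
    length_scale: float,
) -> np.ndarray:
    """Smooth shared pattern field over a patch with item covariance ``S``.

    The field is a low-rank combination of smooth spatial modes — samples of
    a stationary Gaussian process (squared-exponential kernel) over the
    patch nodes, standardized — each loaded with an item vector drawn from
    ``N(0, S)``.  Smoothness emulates spatially graded representations and
    keeps fine-grained (high-k) cluster solutions from being artificially
    reproducible; stationarity keeps the representational amplitude
    homogeneous within a patch, so a patch is one prototype, not several.
    """
    n_nodes = len(coords)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    K = np.exp(-d2 / (2.0 * length_scale**2)) + 1e-8 * np.eye(n_nodes)
    Lk = np.linalg.cholesky(K)
    Phi = Lk @ rng.normal(size=(n_nodes, n_modes))
    Phi = Phi - Phi.mean(axis=0)
    sd = Phi.std(axis=0)
    sd[sd == 0] = 1.0
    Phi = Phi / sd
    C = _similarity_root(S) @ rng.normal(size=(len(S), n_modes))
    G = (C @ Phi.T) / np.sqrt(n_modes)                 # (n_items, n_nodes)
    return np.sqrt(snr) * G


# --------------------------------------------------------------------------
# study simulation
# --------------------------------------------------------------------------

def _default_labels(config: StudyConfig) -> CategoryLabels:
    item_ids = tuple(f"item{i + 1:02d}" for i in range(config.n_items))
    cats = []
    for name, n in zip(config.category_names, config.category_sizes):
        cats.extend([name] * n)
    return CategoryLabels(item_ids=item_ids, categories=tuple(cats))


def _patch_nodes(
    mesh: WholeBrainSurface, spec: PlantedRegionSpec, support_erosion: int
) -> tuple[np.ndarray, np.ndarray]:
    """Declared patch nodes and the eroded pattern-signal support.

    The declared region is the k-ring ball around the patch center; the
    pattern-level signal is implanted only on the ball eroded by
    ``support_erosion`` rings, so that the set of searchlight centers whose
    patches see signal coincides with the declared region rather than its
    searchlight-dilated halo.
    """
    hemi = mesh.left if spec.hemisphere == "left" else mesh.right
    d = np.asarray(spec.center_direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    center = int(np.argmax(hemi.node_coords @ d))
    declared = hemi.k_ring_members(center, spec.patch_rings)
    support = hemi.k_ring_members(center, max(spec.patch_rings - support_erosion, 0))
    if spec.hemisphere == "right":
        declared = declared + mesh.node_index_offset
        support = support + mesh.node_index_offset
    return declared, support


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a configuration.

    Bit-reproducible for a fixed config; all randomness derives from
    ``config.seed`` through independent named substreams.
    """
    labels = _default_labels(config)
    ss = np.random.SeedSequence(int(config.seed))
    seed_images, seed_protos, seed_noise = ss.spawn(3)

    images = generate_stimulus_images(
        labels, seed=int(seed_images.generate_state(1)[0] % (2**31)), size=config.image_size
    )
    bank = default_gabor_bank()
    visual_model = visual_model_dm(images, bank)
    category_model = category_model_dm(labels)

    mesh = build_whole_brain_surface(config.mesh_divisions)
    specs = config.planted_regions or config.default_planted_regions()
    patches = []
    supports = {}
    for spec in specs:
        declared, support = _patch_nodes(mesh, spec, config.support_erosion)
        patches.append((spec, declared))
        supports[spec.name] = support
    seen: set[int] = set()
    for spec, nodes in patches:
        overlap = seen.intersection(nodes.tolist())
        if overlap:
            raise ConfigError(f"planted region {spec.name} overlaps another planted region")
        seen.update(nodes.tolist())

    proto_rng = np.random.default_rng(seed_protos)
    both_models = [category_model, visual_model]
    prototypes = {}
    shared_fields = {}
    targets = {}
    all_coords = np.concatenate([mesh.left.node_coords, mesh.right.node_coords])
    e = mesh.left.edges()
    mean_edge = float(
        np.linalg.norm(
            mesh.left.node_coords[e[:, 0]] - mesh.left.node_coords[e[:, 1]], axis=1
        ).mean()
    )
    for spec, _ in patches:
        n_feat = len(supports[spec.name])
        if spec.role == "expert_category":
            proto = planted_dm_prototype(
                category_model, config.snr, n_features=n_feat,
                model_weight=config.model_weight, rng=proto_rng,
                exclude_models=both_models,
            )
            targets[spec.name] = "mechanical_category"
        elif spec.role == "both_visual":
            proto = planted_dm_prototype(
                visual_model, config.snr, n_features=n_feat,
                model_weight=config.model_weight, rng=proto_rng,
                exclude_models=both_models,
            )
            targets[spec.name] = "visual_similarity"
        elif spec.role == "novice_only":
            proto = _arbitrary_prototype(
                config.n_items, config.snr, n_feat, proto_rng,
                exclude_models=both_models,
            )
            targets[spec.name] = "non_model"
        else:
            raise ConfigError(f"unknown planted-region role {spec.role!r}")
        prototypes[spec.name] = proto
        shared_fields[spec.name] = _spatial_field(
            proto.target_similarity,
            all_coords[supports[spec.name]],
            config.n_spatial_modes,
            proto_rng,
            config.snr,
            length_scale=2.0 * mean_edge,
        )

    n_exp, n_nov = config.group_sizes
    subject_ids = tuple(
        [f"expert{i + 1:02d}" for i in range(n_exp)]
        + [f"novice{i + 1:02d}" for i in range(n_nov)]
    )
    groups = {s: ("expert" if s.startswith("expert") else "novice") for s in subject_ids}

    role_groups = {
        "expert_category": ("expert",),
        "both_visual": ("expert", "novice"),
        "novice_only": ("novice",),
    }
    noise_rng = np.random.default_rng(seed_noise)
    betas = {}
    for sid in subject_ids:
        b = noise_rng.normal(scale=config.noise_sd, size=(config.n_items, mesh.n_nodes))
        for spec, _ in patches:
            if groups[sid] in role_groups[spec.role]:
                b[:, supports[spec.name]] += shared_fields[spec.name]
        betas[sid] = b

    role_nodes = {
        role: np.sort(
            np.concatenate([nodes for spec, nodes in patches if spec.role == role] or [np.array([], dtype=np.int64)])
        )
        for role in ROLES
    }
    planted_k = {
        role: sum(1 for spec, _ in patches if spec.role == role) for role in ROLES
    }
    return SyntheticStudy(
        config=config,
        mesh=mesh,
        subject_ids=subject_ids,
        groups=groups,
        betas=betas,
        labels=labels,
        images=images,
        category_model=category_model,
        visual_model=visual_model,
        ground_truth=GroundTruth(
            role_nodes=role_nodes,
            patches=patches,
            planted_k=planted_k,
            prototype_targets=targets,
        ),
    )
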