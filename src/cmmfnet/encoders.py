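"""The two modality encoders.

The CT encoder (CTE) is a 3D vision transformer: the crop is cut into
non-overlapping patch-size^3 blocks, each flattened and linearly embedded;
the lesion box's six crop-relative coordinates are embedded through a linear
map into a dedicated token prepended to the patch sequence; a learnable
positional table is added and the stack runs through pre-norm transformer
blocks; the final-layer tokens are mean-pooled into a single D-vector.

The clinical encoder (CLE) scales a learned embedding row per record entry,
adds a learnable positional table, and projects the flattened l x D matrix
to a D-vector, so every clinical field keeps its identity up to the final
projection.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat
from .config import ModelConfig
from .nn import Linear, Module, TransformerBlock, trunc_normal
from .types import BBox3D, CROP_RELATIVE


def patch_grid_counts(crop_shape, patch_size: int) -> tuple[int, int, int]:
    """Number of patch blocks per axis: ceil(extent / patch_size)."""
    return tuple(int(np.ceil(s / patch_size)) for s in crop_shape)


def n_patches(crop_shape, patch_size: int) -> int:
    nx, ny, nz = patch_grid_counts(crop_shape, patch_size)
    return nx * ny * nz


def extract_patches(grid: np.ndarray, patch_size: int) -> np.ndarray:
    """Split a (possibly batched) grid into flattened p^3 patch vectors.

    The grid is zero-padded up to multiples of the patch size; patch order
    is lexicographic over (x-block, y-block, z-block).  Returns
    (..., N, p^3).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty grid")
    batched = grid.ndim == 4
    if not batched:
        grid = grid[None]
    if grid.ndim != 4:
        raise ValueError("grid must be rank 3 (or rank 4 with a batch axis)")
    p = int(patch_size)
    b, w, h, d = grid.shape
    nx, ny, nz = (int(np.ceil(s / p)) for s in (w, h, d))
    padded = np.zeros((b, nx * p, ny * p, nz * p))
    padded[:, :w, :h, :d] = grid
    blocks = padded.reshape(b, nx, p, ny, p, nz, p)
    blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6)   # (b, nx, ny, nz, p, p, p)
    patches = blocks.reshape(b, nx * ny * nz, p ** 3)
    return patches if batched else patches[0]


def patch_embed_3d(grid: np.ndarray, projection: Linear,
                   patch_size: int) -> Tensor:
    """Embed a normalized crop into N patch tokens of dimension D."""
    patches = extract_patches(grid, patch_size)
    return projection(Tensor.const(patches))


def bbox_to_vector(bbox: BBox3D | np.ndarray) -> np.ndarray:
    """Validated (x, y, z, w, h, d) vector(s) with all entries in [0, 1]."""
    if isinstance(bbox, BBox3D):
        if bbox.frame != CROP_RELATIVE:
            raise ValueError("bbox token requires a crop-relative box")
        vec = bbox.as_vector()
    else:
        vec = np.asarray(bbox, dtype=np.float64)
    if vec.shape[-1] != 6:
        raise ValueError("bbox vector must have six components")
    if np.any(vec < -1e-9) or np.any(vec > 1.0 + 1e-9):
        raise ValueError("crop-relative bbox coordinates must lie in [0, 1]")
    return vec


def embed_bbox(bbox: BBox3D | np.ndarray, projection: Linear) -> Tensor:
    """Linearly map the six box coordinates to a single D-dim token."""
    return projection(Tensor.const(bbox_to_vector(bbox)))


class CTEncoder(Module):
    """3D ViT over one crop scale, with an optional bounding-box token.

    ``blocks``, ``patch_proj`` and ``bbox_proj`` may be passed in to share
    transformer weights between the two CT scales; the positional table is
    always scale-specific because the token counts differ.
    """

    def __init__(self, config: ModelConfig, crop_shape,
                 rng: np.random.Generator, use_bbox_token: bool = True,
                 blocks: list[TransformerBlock] | None = None,
                 patch_proj: Linear | None = None,
                 bbox_proj: Linear | None = None):
        super().__init__()
        self.crop_shape = tuple(int(c) for c in crop_shape)
        self.patch_size = config.patch_size
        self.use_bbox_token = use_bbox_token
        self.n_patches = n_patches(self.crop_shape, self.patch_size)
        d = config.embed_dim
        self.patch_proj = patch_proj if patch_proj is not None else \
            Linear(self.patch_size ** 3, d, rng)
        if use_bbox_token:
            self.bbox_proj = bbox_proj if bbox_proj is not None else \
                Linear(6, d, rng)
        n_tokens = self.n_patches + (1 if use_bbox_token else 0)
        self.pos = Tensor(trunc_normal(rng, (n_tokens, d)), requires_grad=True)
        self.blocks = blocks if blocks is not None else [
            TransformerBlock(d, config.n_heads, rng,
                             mlp_ratio=config.mlp_ratio)
            for _ in range(config.depth)]

    def __call__(self, grids: np.ndarray,
                 bbox_vecs: np.ndarray | None = None) -> Tensor:
        """grids: (B, w, h, d) normalized crops; bbox_vecs: (B, 6) relative
        boxes.  Returns the (B, D) token-mean feature."""
        grids = np.asarray(grids, dtype=np.float64)
        if grids.ndim == 3:
            grids = grids[None]
        if tuple(grids.shape[1:]) != self.crop_shape:
            raise ValueError(f"expected crops of shape {self.crop_shape}, "
                             f"got {tuple(grids.shape[1:])}")
        tokens = patch_embed_3d(grids, self.patch_proj, self.patch_size)
        if self.use_bbox_token:
            if bbox_vecs is None:
                raise ValueError("this encoder requires bbox vectors")
            vecs = bbox_to_vector(bbox_vecs)
            if vecs.ndim == 1:
                vecs = vecs[None]
            bbox_tok = self.bbox_proj(Tensor.const(vecs[:, None, :]))
            tokens = concat([bbox_tok, tokens], axis=1)
        if tokens.shape[1] != self.pos.shape[0]:
            raise ValueError(f"positional table length {self.pos.shape[0]} "
                             f"does not match token count {tokens.shape[1]}")
        x = tokens + self.pos
        for block in self.blocks:
            x = block(x)
        return x.mean(axis=1)


def cte_forward(encoder: CTEncoder, grid: np.ndarray,
                bbox: BBox3D | np.ndarray | None = None) -> Tensor:
    """Single-case convenience wrapper: returns the 1 x D feature."""
    vec = None
    if bbox is not None:
        vec = bbox_to_vector(bbox)[None]
    grid = np.asarray(grid, dtype=np.float64)
    return encoder(grid[None] if grid.ndim == 3 else grid, vec)


class ClinicalEncoder(Module):
    """Fully connected clinical encoder: per-field embedding rows scaled by
    field values, learnable positions, then flatten + linear to D."""

    def __init__(self, ehr_len: int, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        if ehr_len < 1:
            raise ValueError("ehr_len must be >= 1")
        self.ehr_len = ehr_len
        self.embed_dim = embed_dim
        self.embed = Tensor(trunc_normal(rng, (ehr_len, embed_dim)),
                            requires_grad=True)
        self.embed_bias = Tensor(np.zeros((ehr_len, embed_dim)),
                                 requires_grad=True)
        self.pos = Tensor(trunc_normal(rng, (ehr_len, embed_dim)),
                          requires_grad=True)
        self.out_proj = Linear(ehr_len * embed_dim, embed_dim, rng)

    def tokens(self, values: np.ndarray) -> Tensor:
        """The pre-projection l x D token matrix (batched: B x l x D)."""
        values = np.asarray(values, dtype=np.float64)
        if values.ndim == 1:
            values = values[None]
        if values.shape[-1] != self.ehr_len:
            raise ValueError(f"expected EHR vectors of length {self.ehr_len}, "
                             f"got {values.shape[-1]}")
        scaled = Tensor.const(values[..., None]) * self.embed
        return scaled + self.embed_bias + self.pos

    def __call__(self, values: np.ndarray) -> Tensor:
        toks = self.tokens(values)
        b = toks.shape[0]
        return self.out_proj(toks.reshape(b, self.ehr_len * self.embed_dim))


def cle_forward(encoder: ClinicalEncoder, values: np.ndarray) -> Tensor:
    return encoder(values)
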