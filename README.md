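# nlm3d

Fully 3D Nonlocal Means (NLM) denoising for volumetric data — MRI volumes,
microscopy stacks, and video sequences treated as 3D arrays (frame index =
z) — with memory-bounded chunking and a multi-worker execution layer whose
every configuration is verified to produce the same output.

## The filter

NLM restores each voxel as a mean of the intensities in a cubic **search
box** V_i around it, weighted by *radiometric* similarity — how alike the
small patches around the two voxels look — rather than spatial proximity.
With ‖·‖₂² the raw sum of squared differences over the aligned
**similarity boxes** (patches) B_i and B_j:

```
Y_i = Σ_{j ∈ V_i} exp(−‖B_j − B_i‖₂² / h²) · X_j
      ─────────────────────────────────────────
      Σ_{j ∈ V_i} exp(−‖B_j − B_i‖₂² / h²)
```

Windows are given by their odd edge lengths (a "search 11³, sim 3³"
configuration has `search_edge=11`, `sim_edge=3`). The filter strength `h`
may be set directly, or derived from the noise level σ and a dimensionless
constant β ≈ 1 via `h² = 2·β·σ²·|V_i|` with `|V_i| = search_edge³`.

Because the cost per voxel is |V_i|·|B_i| operations, large volumes are
split along z into chunks sized against a memory budget (half the capacity,
since input and output coexist), each extended by a **halo** of
`search_radius + sim_radius` extra slices on interior sides. That halo is
exactly what makes chunked filtering reproduce unsplit filtering — here,
bit-for-bit — so the same code scales from a laptop test to a
memory-limited device without changing the answer. Two work mappings are
provided (`column`: one task per (x, y) column sweeping z; `voxel`: one
fully vectorised sweep) plus 1..G parallel workers; all configurations are
contractually output-equivalent.

## Worked example

```bash
# make a brain-like phantom (64×64×48, intensities 0–255) + Gaussian noise
nlm3d synth --shape 64,64,48 --noise gaussian --sigma 20 --seed 1 \
      --out-clean clean.npy --out-noisy noisy.npy

# denoise with search 7³, sim 3³, h² = 2·1·20²·7³, and report quality
nlm3d denoise --input noisy.npy --output denoised.npy \
      --search-edge 7 --sim-edge 3 --beta 1 --sigma 20 \
      --metrics-against clean.npy
```

The second command prints (numbers from this exact run):

```json
{
  "mse": 142.66858531963607,
  "psnr_db": 24.477316364634646,
  "max_abs_diff": 48.65922773707203,
  "relative_max_diff": 0.24329613868536015,
  "lag1_autocorr": [
    0.5569535704757455,
    0.5569600807803621,
    0.42429173670752945
  ]
}
```

MSE to the clean truth drops from 400 (= σ²) in the input to ≈ 143, i.e.
the filter removes roughly two thirds of the noise energy at these
settings (PSNR uses the clean volume's peak intensity, 200); the residual
autocorrelation reflects the smooth tissue boundaries where the remaining
error concentrates. The same run with `--workers 4`, with
`--mode column`, or with a `--memory-budget-bytes` small enough to force
several chunks writes an identical volume.

Chunk planning can be inspected without filtering:

```bash
nlm3d plan --shape 8,8,40 --search-edge 5 --sim-edge 3 \
      --memory-budget-bytes 12032 --bytes-per-voxel 4
```

which reports 2 chunks with cores [0, 20) and [20, 40) reading slabs
[0, 23) and [17, 40) — 23 slices being what half of 12032 bytes holds.

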