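# Methods

## Problem and model

Atomic coordinates in macromolecular structure files are real numbers in
Ångstrom with exactly three decimals. `mmcompress` treats compression as a
three-stage pipeline — encoding, packing, entropy compression — where the
encoding stage is the only domain-specific part: it uses the geometry of
polymers (bond-length-scale steps between consecutive atoms) and the
redundancy of homogeneous molecule sets (ensembles, repeated subunits) to
produce integer streams dominated by small values.

"Lossless" is defined on the quantized grid: with factor 1000 every
3-decimal coordinate is represented exactly and reconstruction is bitwise;
with factor 10 (lossy) the grid is 0.1 Å and the rounding rule bounds the
per-coordinate error by half a quantum, 0.05 Å.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| quantization factor | 1000 (lossless) / 10 (lossy) | Å × factor → integer grid |
| strategy | `delta` | best size/complexity trade-off of the intramolecular encoders |
| packing width | 16-bit recursive indexing | nearly all delta values fit 16 bits at factor 1000 |
| gzip level | 9, mtime pinned to 0 | reproducible, byte-identical output |
| traversal | `waterfall` | near-optimal for ensembles without the cost of building a weight graph |
| edge metric | RMSD | MST weights; gzip-size metric available, no material difference observed |
| superposition | on | required for unaligned models and subunit complexes |

## Numerical choices

- **Rounding** is half-away-from-zero (`trunc(x + copysign(0.5, x))`), so
  ±0.0005 quantize symmetrically. Quantizing gemmi's parsed doubles is exact
  for 3-decimal input: the nearest double to a 3-decimal value times 1000 is
  always within 2⁻²⁰ of the integer, far from the 0.5 rounding boundary, so
  no text-level integer parsing is needed.
- **Delta/predictive seams.** The axis-major array is encoded in one pass;
  the two values at axis boundaries are ordinary (large) differences. The
  predictive encoder stores s₀ = c₀ and s₁ = c₁ − c₀, which makes it equal
  to delta∘delta only from index 2 on; its inverse is therefore a seeded
  double cumulative sum.
- **Wavelet.** Single-level CDF 5/3 lifting with whole-point symmetric
  extension, applied after delta encoding. One level keeps the transform
  simple and exactly invertible; symmetric extension means an even-length
  linear ramp keeps one nonzero boundary detail (the mirror breaks
  linearity) while odd-length ramps annihilate completely.
- **Unit-vector codes** use a folded-octahedron layout: the direction is
  projected onto the L1 sphere, the lower hemisphere folded outward, and the
  square coordinates quantized to half the code bits each (layout version 1
  in the container header). Measured over 10⁵ random directions the 16-bit
  grid has 0.94° worst-case / 0.33° mean error — close to the counting
  bound of ~0.6° worst-case for *any* 65536-code layout. Per-axis integer
  corrections make decoding bitwise exact regardless; the bond length is
  stored once as a molecule mean plus per-bond integer residuals.
- **Recursive indexing** treats the open interval (−32768, 32767) as
  self-representing; a value equal to an endpoint emits the endpoint
  followed by an explicit 0 so the decoder always terminates. This makes
  the packer total and bijective over int32 (int32 min expands to 65537
  shorts — pathological but correct).
- **VLQ** encodes each value's raw 32-bit two's-complement pattern in
  big-endian base-128 groups, following the classic unsigned scheme;
  negative values cost five bytes. This is deliberate: difference streams
  are ~half negative, which is precisely why recursive indexing packs them
  ~20% tighter after gzip (and ~70% tighter before) on our fixtures — a
  signed remapping would erase the effect the comparison is meant to show.
- **Superposition** uses the least-squares fit (Kabsch via
  `scipy.spatial.transform.Rotation.align_vectors`), always a proper
  rotation. Collinear or <3-atom inputs fall back to a centroid translation
  with a warning. For exactness, the encoder differences the target against
  the *decoder's* view of the reference: dequantize, apply the stored
  transform (serialized as 3+4 little-endian doubles, 24+32 bytes), and
  re-quantize — so residuals cancel bitwise on both sides. Transform bytes
  are excluded from the compressed-size metric, which counts payload blocks
  only.
- **Intermolecular prediction.** The predictive base stores the change of
  the per-pair residual along the traversal chain — algebraically the
  second-order prediction c⁽ᵏ⁾ − (2c⁽ᵏ⁻¹⁾ − c⁽ᵏ⁻²⁾) in the transformed
  frames — and degrades to plain delta wherever the reference is the chain
  start (so reference-first traversal makes both bases identical).
- **MST determinism.** Prim's algorithm breaks weight ties toward the
  lowest vertex index; the diameter endpoints found by double BFS break
  ties the same way; branches off the diameter path are emitted in BFS
  order, children lowest-index first. Plans are therefore reproducible.

## Synthetic data

The generators produce what the codecs exploit and nothing more: random
walks with bond steps ~ Normal(1.5, 0.05) Å (clipped positive, isotropic
directions), ensembles as one base walk plus per-model Gaussian noise
(default σ = 0.1 Å; 0.05 Å in the benchmark fixtures) with optional random
rigid motions, and complexes as rigid-transformed subunit copies. All
coordinates are rounded to 3 decimals at generation so the lossless
contract is testable, and every generator is a pure function of its seed.

What they do *not* model: covalent geometry beyond bond length (no angles,
no Ramachandran statistics), side chains, excluded volume, or B-factors.
Passing tests therefore demonstrate correctness (exact round trips,
bijective packers, recovered transforms) on data with realistic *step
statistics*; absolute compressed sizes on real archive structures will
differ, although the observed orderings (delta < integer < float;
intermolecular < intramolecular on ensembles; recursive indexing < VLQ)
follow from value-distribution arguments that carry over.

## Problem sizes

The default suite exercises ~200 fixtures of 10–2000 atoms across every
strategy (about 1500 compress/decompress round trips), 10⁶-value packer
sweeps, and exhaustive spanning-tree enumeration up to 6 molecules; the
whole suite runs in under a minute on one core. The packer sweep draws
recursive-indexing inputs from a mixed-scale distribution (94% 16-bit, 5%
±10⁶, 1% ±10⁸ plus all int32 boundary values) because uniform full-range
int32 inputs expand to ~16k shorts each by construction; VLQ, which has no
such expansion, is additionally swept over uniform full-range values.

## Known limitations

- Intermolecular coding requires strict homogeneity (equal atom counts and
  per-position names); near-identical subunits that would need sequence
  alignment to pair atoms are out of scope.
- Only the first alternate location of an atom is kept; occupancies and
  B-factors are not carried through the container.
- Multi-level wavelet decomposition and inter-frame (trajectory) codecs are
  not implemented.
- The container stores atom metadata as gzipped JSON; it is compact enough
  at desk scale but is not a wire-format proposal.
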