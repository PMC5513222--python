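# gielisleaf

Fit a two-parameter polar leaf-shape model to digitized leaf boundaries
and use its goodness of fit as a quantitative test of bilateral symmetry.

Many monocot foliage leaves — bamboo leaves are the archetype — are
lanceolate and mirror-symmetric about the tip–base axis.  Their outline
is captured remarkably well by a simplified Gielis superformula in polar
coordinates,

    r(φ) = l · (|cos(φ/4)| + |sin(φ/4)|)^(−1/n),

with just two parameters: the tip radius **l** (cm), which sets size, and
the dimensionless **leaf-shape parameter n**, which sets the
width-to-length proportion (n ≈ 0.02 for linear-lanceolate blades up to
n ≈ 0.1 for broader ones).  The curve is bilaterally symmetric by
construction — r(φ) = r(−φ) — so the coefficient of determination R² of
a fit to a real boundary measures how mirror-symmetric the blade is.
Length, width, aspect ratio and area follow from the fitted parameters
in closed form or by quadrature; in particular the blade length obeys
L = (1 + 2^(−1/(2n)))·l.

The package provides:

- `geometry` — the forward model (simplified and general superformula)
  and its derived functionals;
- `fitting` — Nelder–Mead estimation of (l, n) plus the rigid pose
  (x₀, y₀, θ) from a boundary, with R² on radii as the symmetry measure;
- `extraction` — calibrated sub-pixel boundary extraction from scanned
  or rendered leaf images (Otsu binarization, marching squares);
- `popstats` — survey statistics: Shapiro–Wilk and Weibull/KS tests of
  leaf-length distributions, median-leaf selection, Tukey HSD comparison
  of shape parameters across species, observed-vs-predicted area
  agreement;
- `synth` — a fully seeded synthetic-data generator (model-true leaves
  with noise, pose, optional one-sided asymmetry; Weibull length
  populations; scan-like masks; multi-species panels);
- a `gielisleaf` command-line tool (`fit`, `extract`, `survey`, `synth`).

## Worked example

```python
import gielisleaf as gl

# a synthetic digitized leaf: true l = 10 cm, n = 0.05, displaced pose,
# 0.5% radial digitization noise
leaf = gl.make_leaf(
    gl.GielisParams(l=10, n=0.05),
    gl.PoseParams(x0=3, y0=-2, theta=0.4),
    noise_sd=0.005, num_points=2000, seed=42,
)

res = gl.fit(leaf)
print(f"l = {res.params.l:.3f} cm, n = {res.params.n:.4f}")
print(f"R^2 = {res.r_squared:.5f}")
f = res.functionals
print(f"L = {f.length:.2f} cm, W = {f.width:.2f} cm, "
      f"W/L = {f.aspect_ratio:.3f}, area = {f.area:.2f} cm^2")
```

Output:

```
l = 10.005 cm, n = 0.0500
R^2 = 0.99998
L = 10.01 cm, W = 1.54 cm, W/L = 0.154, area = 10.57 cm^2
```

The fit recovers both model parameters to a fraction of a percent, and
R² ≈ 0.9999 says the boundary is (as constructed) bilaterally symmetric
up to digitization noise: an asymmetric blade — try
`gl.make_leaf(..., asymmetry=0.05)` — scores visibly lower.  The derived
functionals translate the fit into the usual morphometric descriptors:
a 10.0 cm blade, 1.5 cm wide, aspect ratio 0.15 (linear-lanceolate),
area 10.6 cm².

The same fit from the shell, given a boundary CSV or a scan:

```bash
gielisleaf fit leaf.csv --out fit.json
gielisleaf fit scan.png --dpi 300 --out fit.json --plot overlay.png
```

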