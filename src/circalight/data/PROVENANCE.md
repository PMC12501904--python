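# Observer table provenance

`observer_tables_synthetic.csv` holds the eight spectral functions used
throughout the package, tabulated on 380-780 nm at 5 nm (81 rows).
These are **synthetic analytic reconstructions**, generated by
`circalight.observers.synthesize_tables()` — not reprints of the
standards tables.  Parameterization (version `synthetic-analytic-v1`):

| column | construction |
|---|---|
| `xbar`, `ybar`, `zbar` | Wyman, Sloan & Shirley (2013) multi-lobe piecewise-Gaussian fits to the CIE 1931 2° color-matching functions (~1 % of peak accuracy) |
| `V` | asymmetric Gaussian pinned to the photopic maximum: V(555) = 1, half-widths 38.2 / 46.7 nm |
| `Vprime` | asymmetric Gaussian for the scotopic curve, unit maximum at the 505 nm grid point (rhodopsin peak ≈ 507 nm), half-widths 38 / 40 nm |
| `Mc` | Govardovskii et al. (2000) A1 pigment nomogram at λmax = 480 nm × crystalline-lens transmittance model, peak-normalized |
| `S` | Govardovskii nomogram at λmax = 419 nm × lens × macular transmittance, peak-normalized |
| `mp` | macular pigment transmittance: 10^(−0.35·g(λ)) with Gaussian absorbance template g centered at 460 nm (σ = 35 nm) |

Lens transmittance: optical density exp(−(λ−380)/55), i.e. ≈ 1.0 at
380 nm decaying with a 55 nm scale; transmittance 10^(−D).

Integrity: `observer_tables_manifest.json` records the SHA-256 of the
CSV; `load_observer_tables()` verifies it on every load, and the test
suite checks the CSV against a fresh analytic regeneration.

Implications: every *relative* property (band positions, opponent-
channel sign structure, locus geometry, all self-consistent round
trips) is preserved, but absolute circadian-light values computed with
these tables differ from those of calculators built on the measured
standards tabulations.  See `docs/methods.md` for the full discussion.
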