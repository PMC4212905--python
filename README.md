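# wingmorph

Landmark-based geometric morphometrics for insect wings: generalized
Procrustes superimposition, Kendall tangent-space statistics, PCA
ordination, linear discriminant analysis with leave-one-out
cross-validation, and Mahalanobis-distance / posterior-probability
assignment of *unknown* wing configurations (typically fossils) to the
taxa of a labeled reference collection.

The package is aimed at systematists and paleoentomologists who digitize
2D landmarks on wing venation (e.g. 18 homologous vein intersections on a
bee forewing) and want a tested, scriptable version of the classical
tps/geomorph-style workflow: validate that the reference taxa are
discriminable, then place a fragmentary fossil within a nested taxonomy
(suprafamily → family → subfamily → tribe) with quantified support.

## The model

A specimen is a configuration of k landmarks in 2D. Non-shape variation is
removed by generalized least-squares (GLS) Procrustes superimposition: every
configuration is centered, scaled to unit centroid size
CS = √Σᵢ‖xᵢ − x̄‖², and rotated (proper rotations only) onto an iteratively
re-estimated consensus. Aligned shapes are projected orthogonally onto the
Euclidean space tangent to Kendall's shape space at the consensus,
x′ = x − (x·c − 1)c, and the adequacy of that linearization is certified by
the near-unit slope/correlation between tangent Euclidean and Procrustes
distances.

Discrimination per taxonomic level is by LDA on the tangent coordinates
(after reduction to the non-null-variance PCA subspace): the generalized
eigenproblem S_b w = λ S_w w, with axes scaled so the pooled within-group
covariance of discriminant scores is the identity. In that whitened space
the Euclidean distance to a group centroid is the Mahalanobis distance D_g,
and an unknown's posterior probability of membership is

    pp_g = π_g exp(−D_g²/2) / Σ_h π_h exp(−D_h²/2)

with priors π proportional to group size by default. Reference-set quality
is summarized by leave-one-out cross-validated hit ratios (HR, percent
correctly re-assigned). Unknowns are superimposed *jointly* with the
reference (GLS is sampling dependent), excluded from every model fit, and
scored a posteriori at each level independently.

A fully parameterized synthetic generator produces hierarchically
structured 18-landmark wing datasets (nested group effects shrinking down
the taxonomy, individual/digitization noise, arbitrary rotation / scale /
translation nuisance) with ground truth, so the whole pipeline is testable
end to end without any specimen data.

## Worked example

```
$ wingmorph simulate --seed 3 --out ref.csv --truth truth.json
wrote 640 specimens to ref.csv

$ wingmorph validate --reference ref.csv --levels suprafamily,tribe --out val.json
suprafamily: HR = 100.0%
tribe: HR = 98.4%
tangent adequacy: slope 1.0000, correlation 1.0000

$ wingmorph assign --reference ref.csv --unknowns unk.csv --out rep.json
unknown1: suprafamily:SF2 (MD=0.46) > family:SF2.F3 (MD=3.63) > subfamily:SF2.F3.S2 (MD=4.69) > tribe:SF2.F3.S2.T1 (MD=5.87)
unknown2: suprafamily:SF2 (MD=1.27) > family:SF2.F3 (MD=2.87) > subfamily:SF2.F3.S1 (MD=4.33) > tribe:SF2.F3.S1.T2 (MD=5.39)
```

The validate step says the simulated reference collection is perfectly
discriminable at suprafamily level and 98.4% at tribe level under
leave-one-out cross-validation, and that tangent-space linearization is
essentially exact (slope and correlation ≈ 1). The assign step places each
unknown at four taxonomic levels; the Mahalanobis distance to the winning
group grows toward finer levels (0.5 → 5.9 discriminant-space units) because
finer groupings leave less within-group variance to absorb an unknown's
idiosyncrasies — the full per-group MD/pp tables are in `rep.json`. Here
both unknowns were simulated from held-out species of known tribes, and
both lineages are recovered exactly.

The same operations are available as a library (`wingmorph.gpa`,
`tangent_project`, `lda_fit`, `loocv`, `assign_unknowns`,
`validate_reference`, `generate`, `make_unknowns`); TPS files are read with
`wingmorph.read_tps`.

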