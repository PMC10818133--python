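# reefdiverge

Population-genomic analysis of sympatric taxa along a divergence
continuum — the workflow used to ask whether co-occurring coral
morphotypes are one species or several, and how they diverged.

Given RAD-seq-style SNP genotypes, the pipeline

1. **filters** variants the way reduced-representation datasets demand
   (biallelic / MAC ≥ 3 / depth 5–100 / missingness, clone removal at
   99% similarity keeping the least-missing member, MAF ≥ 0.01, VIF-2
   linkage pruning in 50-SNP windows);
2. **detects sympatric taxa** via PCA + K-means and the multimodality
   ("barcode gap") of within-reef pairwise genetic distances;
3. **quantifies divergence** with Weir–Cockerham F_ST (ratio of sums
   over loci) and pixy-style windowed D_XY that counts invariant sites;
4. **fits divergence histories** on the folded joint allele-frequency
   spectrum (JAFS) under five models — strict isolation (SI),
   isolation-with-migration (IM), IM with two migration classes (IM2M:
   a proportion *Q* of loci migrates at a reduced rate *m_e*, capturing
   genomic semi-permeability), secondary contact (SC) and ancient
   migration (AM) — using its own diffusion-approximation engine,
   Poisson composite likelihood with profiled θ, multi-round
   perturbation optimisation, AIC comparison, Fisher-information SDs and
   Godambe-adjusted likelihood-ratio tests;
5. **converts** fitted scaled parameters into individuals, years and
   migrants per generation via N_ref = θ/(4μL), m = M/(2N_ref),
   T = T_scaled·2·N_ref·T_gen, M21 = m·ν₁, M12 = m·ν₂;
6. **tests niche partitioning** with a partial redundancy analysis of
   Hellinger-transformed allele frequencies on environmental variables,
   conditioned on dbMEM spatial eigenvectors, with forward selection,
   permutation inference and variance partitioning.

A seeded structured-coalescent generator (`reefdiverge.simdata`)
produces RAD-tag genotypes, clonal/missing-data artefacts and spatially
autocorrelated environmental fields under all five histories, and serves
as the independent Monte-Carlo oracle against which the diffusion engine
is validated. It is first-class, tested code — every downstream method
in the package is scored against simulations with known truth.

## Worked example

Simulate a two-class gene-flow history, filter, build the spectrum, fit
and convert:

```python
import reefdiverge as rd

sc = rd.SimScenario("IM2M", nu1=1.5, nu2=1.0, T_total=1.0,
                    M=2.0, M_e=0.05, Q=0.3,
                    n1=10, n2=10, n_tags=2000, theta_per_tag=0.4, seed=7)
ds = rd.simulate_pair(sc)
spec = rd.build_jafs(ds.genotypes, ("pop1", "pop2"), projection=(14, 14))

im = rd.DemographicModel("IM", rounds=(1,), runs_per_round=3,
                         pts=(40,), timescale_factor=2e-3, seed=7).fit(spec)
im2m = rd.DemographicModel("IM2M", rounds=(1,), runs_per_round=3,
                           pts=(40,), timescale_factor=2e-3, seed=7,
                           start=im.params_.__class__(
                               "IM2M", nu1=im.params_.nu1,
                               nu2=im.params_.nu2, T=im.params_.T,
                               M=im.params_.M, M_e=0.1 * im.params_.M,
                               Q=0.2)).fit(spec)
print(rd.compare_models([im.result_, im2m.result_]))

L = rd.total_seq_length(rd.SeqLengthSpec(
    snp_dadi=spec.provenance["n_sites_used"],
    snp_original=ds.genotypes.n_sites,
    n_rad_tags=2000, rad_tag_length=110))
conv = rd.convert(im2m.params_, im2m.theta_, L)
print(f"N_ref={conv.N_ref:.0f}  T={conv.T_years/1e6:.2f} My  "
      f"M21={rd.round_sig(conv.M21)}  M12={rd.round_sig(conv.M12)}")
```

which prints (seed 7):

```
  model      loglik         aic   delta_aic  tie_with_best  n_free_params
0  IM2M -269.484236  552.968471    0.000000           True              7
1    IM -417.827245  845.654490  292.686019          False              5
N_ref=73053  T=0.47 My  M21=1.7  M12=0.98
```

The two-class model wins decisively (ΔAIC ≈ 293), as it should on
IM2M-generated data; the fitted history converts to an ancestral size of
~73,000 individuals, a split roughly half a million years old and one to
two migrants per generation — and the truth here was M·ν₁/2 = 1.5
migrants into population 1, so the conversion chain lands where it
should.

The same flow is scriptable: `reefdiverge simulate | filter | stats |
jafs | fit | convert | rda | run` (see `reefdiverge --help`); `run`
executes a YAML-configured pipeline and writes a manifest whose
checksums are bit-identical on re-run.

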