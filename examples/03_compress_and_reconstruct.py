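"""Compressed sensing round trip: sense at CR 0.7 and recover with all solvers.

An exactly-100-sparse coefficient vector in a 1024-dimensional DCT basis is
observed through a Gaussian matrix with M = 717 rows, then reconstructed with
OMP (needs the true sparsity), SWOMP (needs a threshold and iteration cap),
and SWAMP (estimates the sparsity itself).
"""

import cardiocs as cc

N, K_SPARSE, CR = 1024, 100, 0.7
domain = cc.dct_domain(N)
theta = cc.make_ksparse(N, K_SPARSE, seed=7)
x = cc.synthesize(domain, theta)
ensemble = cc.gaussian_ensemble(N, CR, seed=11)
obs = cc.sense(ensemble, x, domain=domain)
a, norms = cc.effective_matrix(ensemble, domain)
print(f"N={N}, M={ensemble.m} measurements (CR={CR})")

for name, run in [
    ("omp", lambda: cc.omp(obs.y, a, sparsity=K_SPARSE)),
    ("swomp", lambda: cc.swomp(obs.y, a, alpha=0.83, max_iterations=20)),
    ("swamp", lambda: cc.swamp(obs.y, a, cc.SwampConfig(alpha=0.83))),
]:
    result = run()
    x_hat = cc.reconstruct_signal(result, domain, column_norms=norms)
    rep = cc.report(x, x_hat)
    print(f"{name:6s} support={len(result.support):3d} stop={result.terminated_by:12s}"
          f" MR={rep.mr:.6f} RMSE={rep.rmse:.2e}")
# MR = 1 means the reconstruction matches the original to machine precision;
# SWAMP reaches it without being told the sparsity.
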