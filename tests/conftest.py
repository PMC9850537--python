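import numpy as np
import pandas as pd
import pytest

import temprrm as t


@pytest.fixture(scope="session")
def small_cfg():
    return t.SimConfig(n_founders=40, n_generations=3, n_snps=120, seed=42,
                       min_records=2, mean_records=3.0, cg_count=8)


@pytest.fixture(scope="session")
def small_herd(small_cfg):
    ped = t.simulate_pedigree(small_cfg)
    geno = t.gene_drop_genotypes(ped, small_cfg)
    pheno, truth = t.simulate_phenotypes(ped, small_cfg)
    return {"cfg": small_cfg, "ped": ped, "geno": geno, "pheno": pheno,
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def random_pedigree_frame(rng):
    """A hand-free random but valid pedigree frame generator."""
    def make(n_founders=10, n_extra=30, seed=0):
        r = np.random.default_rng(seed)
        rows = [{"animal": i + 1, "sire": 0, "dam": 0}
                for i in range(n_founders)]
        ids = list(range(1, n_founders + 1))
        for k in range(n_extra):
            s, d = r.choice(ids, size=2, replace=False)
            rows.append({"animal": n_founders + k + 1, "sire": int(s),
                         "dam": int(d)})
            ids.append(n_founders + k + 1)
        return pd.DataFrame(rows)
    return make
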