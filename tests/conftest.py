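import textwrap

import pytest

from splicescreen import ScreenDesign, generate_screen


@pytest.fixture
def toy_library_csv(tmp_path):
    """Two genes x three siRNAs plus the two control records."""
    path = tmp_path / "library.csv"
    path.write_text(textwrap.dedent("""\
        sirna_id,gene_symbol,gene_ncbi_id,role
        GENE0001_si1,GENE0001,100001,library
        GENE0001_si2,GENE0001,100001,library
        GENE0001_si3,GENE0001,100001,library
        GENE0002_si1,GENE0002,100002,library
        GENE0002_si2,GENE0002,100002,library
        GENE0002_si3,GENE0002,100002,library
        siNEG,CONTROL,,negative_control
        siPOS,CONTROL,,positive_control
    """))
    return path


@pytest.fixture
def small_screen():
    """Noise-free 20-gene screen with three full-strength effector genes."""
    design = ScreenDesign(
        n_genes=20, sirnas_per_gene=3, noise_sd=0.0, plate_factor_sd=0.0, seed=7,
        effect_table={"GENE0001": -1.0, "GENE0005": 1.0, "GENE0011": -1.0},
    )
    return generate_screen(design)


@pytest.fixture
def noisy_screen():
    """Default-noise 50-gene screen with 10 positive-control-sized effectors."""
    effectors = {f"GENE{i:04d}": -1.0 for i in range(1, 11)}
    design = ScreenDesign(
        n_genes=50, sirnas_per_gene=3, noise_sd=0.1, seed=11, effect_table=effectors)
    return generate_screen(design)
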