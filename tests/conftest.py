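import numpy as np
import pytest

from scoliofe import materials, morphing, synth, template


def make_box_model(nx=1, ny=1, nz=1, size=(1.0, 1.0, 1.0), E=100.0, nu=0.3):
    """Axis-aligned hex block with no springs, for solver unit tests."""
    sx, sy, sz = size
    xs = np.linspace(0, sx, nx + 1)
    ys = np.linspace(0, sy, ny + 1)
    zs = np.linspace(0, sz, nz + 1)
    pts = np.array([[x, y, z] for z in zs for y in ys for x in xs])
    ids = np.arange(len(pts)).reshape(nz + 1, ny + 1, nx + 1)
    cells = []
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                cells.append([
                    ids[iz, iy, ix], ids[iz, iy, ix + 1],
                    ids[iz, iy + 1, ix + 1], ids[iz, iy + 1, ix],
                    ids[iz + 1, iy, ix], ids[iz + 1, iy, ix + 1],
                    ids[iz + 1, iy + 1, ix + 1], ids[iz + 1, iy + 1, ix],
                ])
    cells = np.array(cells, dtype=int)
    m = template.HexMeshModel(
        nodes=pts, hexes=cells,
        structure=np.array(["vertebra"] * len(cells), dtype=object),
        level=np.array(["T1"] * len(cells), dtype=object),
        region=np.array(["body_ant_left"] * len(cells), dtype=object))
    m.elem_E = np.full(len(cells), float(E))
    m.elem_nu = np.full(len(cells), float(nu))
    m.grid_ids = ids
    return m


@pytest.fixture(scope="session")
def straight_template():
    return template.build_template()


@pytest.fixture(scope="session")
def straight_landmarks(straight_template):
    return template.extract_landmarks(straight_template)


@pytest.fixture(scope="session")
def scoliotic_patient():
    """Default synthetic 40-degree patient bundle."""
    return synth.generate_patient(synth.SynthSpec(timepoints=[0.0, 1.0]))


@pytest.fixture(scope="session")
def scoliotic_model(straight_template, scoliotic_patient):
    model = morphing.morph_model(straight_template,
                                 scoliotic_patient["landmarks"])
    cards = materials.default_cards(age=scoliotic_patient["profile"].age)
    materials.assign_materials(model, cards,
                               scoliotic_patient["profile"].flexibility)
    return model
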