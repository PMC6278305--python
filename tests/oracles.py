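"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: the frame
oracle builds an explicit rotation matrix by Gram-Schmidt and applies its
transpose; the twist-angle oracle computes plane normals with hand-written
cross products and classic arccos formulas, in plain Python floats.
"""

from __future__ import annotations

import math

# Standard atomic masses (u), written out so the oracle does not import the
# package's mass table.
MASS_N = 14.0067
MASS_O = 15.9994


def _sub(a, b):
    return [a[0] - b[0], a[1] - b[1], a[2] - b[2]]


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _cross(a, b):
    return [
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ]


def _norm(a):
    return math.sqrt(_dot(a, a))


def _scale(a, s):
    return [a[0] * s, a[1] * s, a[2] * s]


def _unit(a):
    return _scale(a, 1.0 / _norm(a))


def nitrite_com_oracle(site):
    total = MASS_N + 2 * MASS_O
    return [
        (MASS_N * site.nitrite_n[i] + MASS_O * (site.nitrite_o1[i] + site.nitrite_o2[i]))
        / total
        for i in range(3)
    ]


def cu_local_oracle(site):
    """Cu in the ligand frame via an explicit Gram-Schmidt rotation matrix."""
    com = nitrite_com_oracle(site)
    v1 = _sub(site.nitrite_n, com)
    v2 = _sub(site.nitrite_o1, com)
    x = _unit(v1)
    y = _unit(_sub(v2, _scale(x, _dot(v2, x))))
    z = _cross(x, y)
    v_cu = _sub(site.cu, com)
    # Sign conventions: non-negative Cu z-component; if Cu is in-plane,
    # non-negative y-component.  Flip y and z together to stay right-handed.
    if _dot(z, v_cu) < -1e-9 or (abs(_dot(z, v_cu)) <= 1e-9 and _dot(y, v_cu) < 0):
        y, z = _scale(y, -1.0), _scale(z, -1.0)
    # Rows of the rotation matrix are the axes; cu_local = R (cu - com).
    return [_dot(x, v_cu), _dot(y, v_cu), _dot(z, v_cu)]


def theta_oracle(site):
    x, _, z = cu_local_oracle(site)
    proj = math.hypot(x, z)
    return math.degrees(math.acos(max(-1.0, min(1.0, x / proj))))


def psi_oracle(site):
    x, y, _ = cu_local_oracle(site)
    proj = math.hypot(x, y)
    return math.degrees(math.acos(max(-1.0, min(1.0, x / proj))))


def phi_oracle(site):
    """Twist angle via explicit plane normals from cross products."""
    cu = list(site.cu)
    nit = _sub(site.nitrite_n, cu)
    his = sorted(site.his_n, key=lambda h: h.residue_number)
    dirs = {h.residue_number: _sub(h.position, cu) for h in his}

    def angle_to_nitrite(v):
        return math.degrees(
            math.acos(max(-1.0, min(1.0, _dot(nit, v) / (_norm(nit) * _norm(v)))))
        )

    ranked = sorted(dirs, key=lambda r: (-angle_to_nitrite(dirs[r]), r))
    axial = ranked[0]
    eq = sorted(r for r in dirs if r != axial)
    n1 = _cross(nit, dirs[axial])
    n2 = _cross(dirs[eq[0]], dirs[eq[1]])
    c = _dot(n1, n2) / (_norm(n1) * _norm(n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def mean_std_oracle(values, sample=False):
    """Two-pass mean and standard deviation in plain Python."""
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    denom = (n - 1) if (sample and n > 1) else n
    return mean, math.sqrt(ss / denom)
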