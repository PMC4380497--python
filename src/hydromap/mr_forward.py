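"""Forward simulation of the five-scan 3T spoiled-GRE water-content protocol.

The protocol comprises: a proton-density weighted GRE scan (TR 1800 ms,
TE 5.2 ms, FA 40 deg), a T1-weighting companion scan (TR 500, TE 5.2, FA 90),
a series of four saturation-free GRE-EPI scans at TE 11 ms and nominal flip
angles 30/60/90/120 deg for transmit-field (B1+) mapping, two low-resolution
GRE scans (TR 500, TE 5.2, FA 40) acquired once with the array coil and once
with the homogeneous body coil for receive-field (B1-) mapping, and an
8-echo GRE (TR 35, FA 12, TE = 2.3 + k*2.27 ms) for T2* mapping.

Signal model: ideally spoiled gradient-echo steady state,

    S = g * b1r * W * sin(b1t*a) * (1 - E1) / (1 - cos(b1t*a) * E1)
        * exp(-TE / T2*),   E1 = exp(-TR / T1),

with global scanner gain g.  No off-resonance, motion, flow or slice-profile
effects: the correction chain addresses exactly B1, T2*, T1 saturation,
residual bias and CSF normalization, so the forward model contains exactly
those physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._utils import rng_from
from .phantom import DigitalPhantom, FieldMaps

#: TR (ms) used for the saturation-free B1-mapping EPI series.  The series
#: isolates sin(b1t * a); simulating it fully relaxed (TR >> T1) realizes the
#: stated purpose of the scans without modelling EPI readout.
B1_SERIES_TR_MS = 20000.0


@dataclass(frozen=True)
class ScanSpec:
    """One acquisition: sequence kind, timing, flip angle, noise, resolution."""

    kind: str = "gre"                    # "gre" | "epi"
    tr_ms: float = 1800.0
    te_ms: tuple = (5.2,)
    fa_deg: float = 40.0
    noise_sd: float = 0.0                # relative to mean brain signal
    downsample: int = 1

    def __post_init__(self):
        if self.kind not in ("gre", "epi"):
            raise ValueError(f"unknown scan kind {self.kind!r}")
        if self.tr_ms <= 0 or any(te <= 0 for te in self.te_ms):
            raise ValueError("TR and all TEs must be positive")
        if not 0 < self.fa_deg <= 180:
            raise ValueError("flip angle must lie in (0, 180]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_protocol(noise_sd: float = 0.02) -> dict:
    """The five-scan protocol with a common relative noise level (SNR 50)."""
    te_me = tuple(2.3 + k * 2.27 for k in range(8))
    return {
        "pd": ScanSpec("gre", 1800.0, (5.2,), 40.0, noise_sd),
        "t1": ScanSpec("gre", 500.0, (5.2,), 90.0, noise_sd),
        "b1": [ScanSpec("epi", B1_SERIES_TR_MS, (11.0,), fa, noise_sd)
               for fa in (30.0, 60.0, 90.0, 120.0)],
        "recv": ScanSpec("gre", 500.0, (5.2,), 40.0, noise_sd, downsample=2),
        "multiecho": ScanSpec("gre", 35.0, te_me, 12.0, noise_sd),
    }


@dataclass
class StudyAcquisition:
    """Simulated volumes of the full protocol, all on the phantom grid."""

    pd_scan: np.ndarray
    t1_scan: np.ndarray
    b1_series: list                      # of (fa_deg, volume)
    recv_array: np.ndarray               # array coil (carries b1r)
    recv_body: np.ndarray                # body coil reference (b1r == 1)
    multiecho: list                      # of volumes, one per echo
    protocol: dict = field(default_factory=default_protocol)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)

    @property
    def multiecho_te_ms(self):
        return self.protocol["multiecho"].te_ms

    @property
    def b1_angles_deg(self):
        return [fa for fa, _ in self.b1_series]

    def scaled(self, gain: float) -> "StudyAcquisition":
        """The same acquisition under a global scanner gain."""
        return replace(
            self,
            pd_scan=self.pd_scan * gain, t1_scan=self.t1_scan * gain,
            b1_series=[(fa, v * gain) for fa, v in self.b1_series],
            recv_array=self.recv_array * gain, recv_body=self.recv_body * gain,
            multiecho=[v * gain for v in self.multiecho])


def spgr_signal(water, t1_ms, t2star_ms, b1t, b1r, scan: ScanSpec,
                echo_index: int = 0, gain: float = 1.0):
    """Ideally spoiled GRE steady-state magnitude signal (arbitrary units).

    Linear in water content, receive sensitivity and gain; vectorized over
    arrays of any matching shape.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    t2s = np.asarray(t2star_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(t2s <= 0):
        raise ValueError("T1 and T2* must be positive")
    alpha = np.deg2rad(scan.fa_deg) * np.asarray(b1t, dtype=float)
    e1 = np.exp(-scan.tr_ms / t1)
    sat = np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    te = scan.te_ms[echo_index]
    return gain * np.asarray(b1r, float) * np.asarray(water, float) \
        * sat * np.exp(-te / t2s)


def saturation_factor(t1_ms, fa_deg, tr_ms, b1t=1.0):
    """sin(b1t*a) * (1-E1) / (1 - cos(b1t*a)*E1): the T1/flip-angle part of
    the spoiled-GRE signal."""
    alpha = np.deg2rad(fa_deg) * np.asarray(b1t, dtype=float)
    e1 = np.exp(-np.asarray(tr_ms, float) / np.asarray(t1_ms, dtype=float))
    return np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def _block_downsample_upsample(vol: np.ndarray, factor: int) -> np.ndarray:
    """Block-average by ``factor`` then nearest-neighbour upsample back."""
    if factor <= 1:
        return vol
    shape = vol.shape
    pad = [(0, (-s) % factor) for s in shape]
    v = np.pad(vol, pad, mode="edge")
    s = v.shape
    v = v.reshape(s[0] // factor, factor, s[1] // factor, factor,
                  s[2] // factor, factor).mean(axis=(1, 3, 5))
    up = np.repeat(np.repeat(np.repeat(v, factor, 0), factor, 1), factor, 2)
    return up[: shape[0], : shape[1], : shape[2]]


def simulate_scan(phantom: DigitalPhantom, fields: FieldMaps, scan: ScanSpec,
                  seed: int = 0, gain: float = 1.0, use_receive: bool = True,
                  rician: bool = False):
    """Simulate one scan; returns a volume, or a list of volumes for
    multi-echo specs.

    Noise is zero-mean Gaussian on the magnitude (SD = noise_sd x mean brain
    signal of the echo), clipped at zero; Rician noise is available by flag.
    Low-resolution scans (downsample > 1) are block-averaged then
    nearest-neighbour upsampled to the phantom grid.
    """
    if fields.b1t.shape != phantom.shape or fields.b1r.shape != phantom.shape:
        raise ValueError("field map grid does not match phantom grid")
    brain = phantom.brain_mask
    b1r = fields.b1r if use_receive else np.ones_like(fields.b1r)
    rng = rng_from(seed, "scan")
    vols = []
    for k in range(len(scan.te_ms)):
        sig = np.zeros(phantom.shape)
        sig[brain] = spgr_signal(
            phantom.truth_water[brain], phantom.truth_t1[brain],
            phantom.truth_t2star[brain], fields.b1t[brain], b1r[brain],
            scan, echo_index=k, gain=gain)
        sig = _block_downsample_upsample(sig, scan.downsample)
        if scan.noise_sd > 0:
            sd = scan.noise_sd * sig[brain].mean()
            if rician:
                sig = np.hypot(sig + rng.normal(0, sd, sig.shape),
                               rng.normal(0, sd, sig.shape))
            else:
                sig = np.clip(sig + rng.normal(0, sd, sig.shape), 0.0, None)
        vols.append(sig)
    return vols if len(vols) > 1 else vols[0]


def simulate_protocol(phantom: DigitalPhantom, fields: FieldMaps,
                      protocol: dict | None = None, seed: int = 0,
                      gain: float = 1.0, rician: bool = False
                      ) -> StudyAcquisition:
    """Simulate the full five-scan protocol with per-scan derived sub-seeds."""
    prot = protocol or default_protocol()
    from ._utils import spawn_seed

    def sub(name, extra=0):
        return spawn_seed(seed, "protocol", name, extra)

    pd_vol = simulate_scan(phantom, fields, prot["pd"], sub("pd"), gain,
                           rician=rician)
    t1_vol = simulate_scan(phantom, fields, prot["t1"], sub("t1"), gain,
                           rician=rician)
    b1_series = [(s.fa_deg, simulate_scan(phantom, fields, s, sub("b1", i),
                                          gain, rician=rician))
                 for i, s in enumerate(prot["b1"])]
    recv_array = simulate_scan(phantom, fields, prot["recv"], sub("recv", 0),
                               gain, use_receive=True, rician=rician)
    recv_body = simulate_scan(phantom, fields, prot["recv"], sub("recv", 1),
                              gain, use_receive=False, rician=rician)
    multiecho = simulate_scan(phantom, fields, prot["multiecho"],
                              sub("multiecho"), gain, rician=rician)
    return StudyAcquisition(pd_scan=pd_vol, t1_scan=t1_vol,
                            b1_series=b1_series, recv_array=recv_array,
                            recv_body=recv_body, multiecho=multiecho,
                            protocol=prot, voxel_size_mm=phantom.voxel_size_mm)


# ---------------------------------------------------------------------------
# on-disk interface

def write_acquisition(acq: StudyAcquisition, outdir) -> None:
    """Write each simulated scan as NIfTI-1 with a JSON sidecar (BIDS-style
    RepetitionTime / EchoTime / FlipAngle, in seconds and degrees)."""
    import json
    from pathlib import Path

    from ._utils import save_nifti

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = acq.voxel_size_mm

    def sidecar(path, spec: ScanSpec, te_ms, fa=None):
        meta = {"RepetitionTime": spec.tr_ms / 1000.0,
                "EchoTime": te_ms / 1000.0,
                "FlipAngle": fa if fa is not None else spec.fa_deg,
                "ScanKind": spec.kind}
        Path(str(path).replace(".nii.gz", ".json")).write_text(
            json.dumps(meta, indent=1))

    save_nifti(acq.pd_scan, outdir / "pd.nii.gz", vs)
    sidecar(outdir / "pd.nii.gz", acq.protocol["pd"], acq.protocol["pd"].te_ms[0])
    save_nifti(acq.t1_scan, outdir / "t1w.nii.gz", vs)
    sidecar(outdir / "t1w.nii.gz", acq.protocol["t1"], acq.protocol["t1"].te_ms[0])
    for i, (fa, vol) in enumerate(acq.b1_series):
        p = outdir / f"b1_fa{int(fa):03d}.nii.gz"
        save_nifti(vol, p, vs)
        sidecar(p, acq.protocol["b1"][i], acq.protocol["b1"][i].te_ms[0], fa)
    save_nifti(acq.recv_array, outdir / "recv_array.nii.gz", vs)
    sidecar(outdir / "recv_array.nii.gz", acq.protocol["recv"],
            acq.protocol["recv"].te_ms[0])
    save_nifti(acq.recv_body, outdir / "recv_body.nii.gz", vs)
    sidecar(outdir / "recv_body.nii.gz", acq.protocol["recv"],
            acq.protocol["recv"].te_ms[0])
    for k, vol in enumerate(acq.multiecho):
        p = outdir / f"multiecho_e{k + 1}.nii.gz"
        save_nifti(vol, p, vs)
        sidecar(p, acq.protocol["multiecho"], acq.protocol["multiecho"].te_ms[k])


def read_acquisition(acq_dir) -> StudyAcquisition:
    """Load an acquisition directory written by :func:`write_acquisition`."""
    import json
    from pathlib import Path

    from ._utils import load_nifti

    d = Path(acq_dir)

    def need(name):
        p = d / name
        if not p.exists():
            raise FileNotFoundError(f"acquisition directory {d} is missing "
                                    f"required scan {name}")
        return load_nifti(p)[0].astype(float)

    me_paths = sorted(d.glob("multiecho_e*.nii.gz"))
    if len(me_paths) < 3:
        raise FileNotFoundError(f"acquisition directory {d} is missing the "
                                "multiecho series (multiecho_e*.nii.gz)")
    b1_paths = sorted(d.glob("b1_fa*.nii.gz"))
    if len(b1_paths) < 3:
        raise FileNotFoundError(f"acquisition directory {d} is missing the "
                                "B1 flip-angle series (b1_fa*.nii.gz)")
    te_ms = []
    for p in me_paths:
        meta = json.loads(Path(str(p).replace(".nii.gz", ".json")).read_text())
        te_ms.append(meta["EchoTime"] * 1000.0)
    prot = default_protocol()
    prot["multiecho"] = replace(prot["multiecho"], te_ms=tuple(te_ms))
    b1_series = []
    for p in b1_paths:
        meta = json.loads(Path(str(p).replace(".nii.gz", ".json")).read_text())
        b1_series.append((float(meta["FlipAngle"]), load_nifti(p)[0].astype(float)))
    return StudyAcquisition(
        pd_scan=need("pd.nii.gz"), t1_scan=need("t1w.nii.gz"),
        b1_series=b1_series, recv_array=need("recv_array.nii.gz"),
        recv_body=need("recv_body.nii.gz"),
        multiecho=[load_nifti(p)[0].astype(float) for p in me_paths],
        protocol=prot)
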