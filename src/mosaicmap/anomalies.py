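"""Detection of contamination, CNVs, gene conversions and unexpected blocks.

All detectors operate on intensities and/or the fitted haplotype map of a
single strain, against the founder reference:

* contamination: non-founder segments found from *noninformative* SNPs
  (both founders share a cluster) whose signal departs from the shared
  cluster, segmented with a two-state HMM;
* CNVs: runs of invariant probes whose average intensity deviates from the
  founder reference by a large t-like statistic;
* gene conversions: isolated host-genotype markers inside donor haplotype
  on the introgressed chromosome of a consomic (CSS) strain;
* unexpected blocks: any haplotype block that contradicts the CSS design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotyping import CALL_A, CALL_B, FounderReference, GenotypeCallSet
from .hmm import F1, F2, HET, HaplotypeMap
from .intensities import IntensityTable

log = logging.getLogger(__name__)

DELETION = "deletion"
DUPLICATION = "duplication"
HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


# ---------------------------------------------------------------------------
# contamination

@dataclass
class ContaminationParams:
    """Two-state (background/contaminated) discordance HMM settings.

    The discordance radius is wider than the genotype-call radius: the scan
    asks whether a signal is *far* from the shared founder cluster, and a
    3-sd radius would flag ~1-3% of clean probes once centre/dispersion
    estimation error is folded in.
    """
    call_radius: float = 4.0
    eps_background: float = 0.005   # discordance rate in clean genome
    eps_contaminated: float = 0.30  # discordance rate inside a contaminated segment
    switch_probability: float = 1e-4
    min_discordant: int = 3         # reporting rule
    null_center: tuple[float, float] = (0.2, 0.0)  # no-signal cluster (deletions)


@dataclass(frozen=True)
class ContaminationCall:
    chrom: str
    start_bp: int  # position of the first noninformative SNP in the segment
    end_bp: int    # position of the last one (internal half-open: end is pos+1)
    n_snps: int
    n_discordant: int

    @property
    def discordance(self) -> float:
        return self.n_discordant / self.n_snps


def detect_contamination(sample_intensities: IntensityTable, sample: str,
                         ref: FounderReference,
                         params: ContaminationParams | None = None,
                         ) -> list[ContaminationCall]:
    """Scan noninformative SNPs for segments discordant with both founders.

    A noninformative SNP is *discordant* when the sample's signal lies
    outside ``call_radius`` dispersions of the shared founder cluster
    (centre = mean of the two founder centres).  A two-state HMM segments
    the discordance sequence; contaminated segments are reported only when
    they contain at least ``min_discordant`` discordant SNPs.
    """
    params = params or ContaminationParams()
    snp = sample_intensities.select_class("snp")
    noninf = ~ref.informative
    if not noninf.any():
        return []
    snp = snp.select_probes(noninf)
    center = 0.5 * (ref.centers1[noninf] + ref.centers2[noninf])
    # robust floor: probes whose replicate sd is understated would otherwise
    # dominate the background discordance rate
    disp = np.maximum(ref.dispersion[noninf], np.median(ref.dispersion[noninf]))
    sig = snp.signal(sample)
    d = np.hypot(sig[:, 0] - center[:, 0], sig[:, 1] - center[:, 1])
    # a signal at the null (no-hybridisation) cluster is a no-call — e.g. a
    # deleted region — not evidence of foreign alleles
    d_null = np.hypot(sig[:, 0] - params.null_center[0],
                      sig[:, 1] - params.null_center[1])
    discordant = (d > params.call_radius * disp) & (d_null > params.call_radius * disp)

    obs = discordant.astype(np.int8)
    log_e = np.log(np.array([[1 - params.eps_background, params.eps_background],
                             [1 - params.eps_contaminated, params.eps_contaminated]]))
    sw = params.switch_probability
    log_t = np.log(np.array([[1 - sw, sw], [sw, 1 - sw]]))

    def viterbi2(seq: np.ndarray) -> np.ndarray:
        delta = np.log(0.5) + log_e[:, seq[0]]
        back = np.empty((len(seq), 2), dtype=np.int8)
        for t in range(1, len(seq)):
            cand = delta[:, None] + log_t
            best = (cand[1] > cand[0]).astype(np.int8)  # prefer background on ties
            back[t] = best
            delta = cand[best, [0, 1]] + log_e[:, seq[t]]
        path = np.empty(len(seq), dtype=np.int8)
        path[-1] = int(np.argmax(delta))
        for t in range(len(seq) - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path

    calls: list[ContaminationCall] = []
    chrom_arr = snp.probes["chrom"].to_numpy()
    pos_arr = snp.probes["pos"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        m = chrom_arr == chrom
        if not m.any():
            continue
        path = viterbi2(obs[m])
        pos = pos_arr[m]
        dis = discordant[m]
        in_seg = path == 1
        changes = np.flatnonzero(in_seg[1:] != in_seg[:-1]) + 1
        bounds = np.concatenate(([0], changes, [len(in_seg)]))
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            if not in_seg[i0]:
                continue
            n_dis = int(dis[i0:i1].sum())
            if n_dis >= params.min_discordant:
                calls.append(ContaminationCall(str(chrom), int(pos[i0]),
                                               int(pos[i1 - 1]) + 1,
                                               int(i1 - i0), n_dis))
    return calls


# ---------------------------------------------------------------------------
# copy number variants

@dataclass
class CnvThresholds:
    t_threshold: float = 5.0   # segment-level t statistic
    probe_z: float = 2.0       # per-probe deviation defining candidate runs
    min_probes: int = 10
    min_length_bp: int = 20_000
    merge_gap_probes: int = 2  # same-direction runs bridged across this many probes
    cnv_law: dict[int, float] = field(default_factory=lambda: {
        0: 0.2, 1: 0.6, 2: 1.0, 3: 1.4, 4: 1.8})


@dataclass(frozen=True)
class CnvCall:
    chrom: str
    start_bp: int
    end_bp: int       # half-open: last probe position + 1
    direction: str    # deletion | duplication
    zygosity: str     # homozygous | heterozygous
    n_probes: int
    segment_t: float  # mean probe z * sqrt(n)


def detect_cnv(sample_intensities: IntensityTable, sample: str,
               ref: FounderReference,
               thresholds: CnvThresholds | None = None) -> list[CnvCall]:
    """Scan invariant probes for copy-number changes relative to founders.

    Per probe, ``z_i = (x_i - mu_i) / sd_i`` against the founder replicate
    statistics.  Maximal runs of same-signed probes with ``|z| > probe_z``
    are candidate segments; a candidate is called when it covers at least
    ``min_probes`` probes, spans more than ``min_length_bp``, and its
    segment statistic ``t = |mean(z)| * sqrt(n)`` exceeds ``t_threshold``.
    (A per-probe ``|z| > 5`` rule would make a one-copy change — a ~5 sd
    mean shift under the default intensity law — undetectable, since each
    probe would clear the threshold only half the time; the t statistic is
    a segment-level quantity.)  Zygosity is assigned by whether the mean
    intensity ratio is nearer the one-copy (or three-copy) law than the
    zero-copy (or four-copy) law.
    """
    th = thresholds or CnvThresholds()
    inv = sample_intensities.select_class("invariant")
    if inv.n_probes == 0 or len(ref.inv_mean) == 0:
        return []
    if not inv.probes["probe_id"].equals(ref.inv_probes["probe_id"]):
        raise ValueError("invariant probe sets differ between sample and reference")
    x = inv.average[inv.sample_row(sample)]
    sd = ref.inv_sd
    usable = sd > 0
    if not usable.all():
        log.warning("excluding %d invariant probes with zero reference sd",
                    int((~usable).sum()))
    z = np.zeros(len(x))
    z[usable] = (x[usable] - ref.inv_mean[usable]) / sd[usable]
    exceed = usable & (np.abs(z) > th.probe_z)

    calls: list[CnvCall] = []
    chrom_arr = inv.probes["chrom"].to_numpy()
    pos_arr = inv.probes["pos"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        m = chrom_arr == chrom
        zm, em, pm, xm, mum = z[m], exceed[m], pos_arr[m], x[m], ref.inv_mean[m]
        sign = np.sign(zm)
        # maximal same-signed runs of qualifying probes ...
        runs: list[list[int]] = []  # [first, last, sign]
        for i in np.flatnonzero(em):
            if runs and runs[-1][2] == sign[i] and i == runs[-1][1] + 1:
                runs[-1][1] = i
            else:
                runs.append([int(i), int(i), int(sign[i])])
        # ... bridged across short gaps (an isolated noise probe inside a
        # real CNV should not split it)
        merged: list[list[int]] = []
        for r in runs:
            if (merged and merged[-1][2] == r[2]
                    and r[0] - merged[-1][1] - 1 <= th.merge_gap_probes):
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        for first, last, sgn in merged:
            idx = np.arange(first, last + 1)
            n = len(idx)
            span = int(pm[last] - pm[first])
            seg_t = float(abs(zm[idx].mean()) * np.sqrt(n))
            if n < th.min_probes or span <= th.min_length_bp or seg_t <= th.t_threshold:
                continue
            direction = DELETION if sgn < 0 else DUPLICATION
            ratio = float(np.mean(xm[idx] / mum[idx]))
            if direction == DELETION:
                zyg = (HETEROZYGOUS if abs(ratio - th.cnv_law[1]) <
                       abs(ratio - th.cnv_law[0]) else HOMOZYGOUS)
            else:
                zyg = (HETEROZYGOUS if abs(ratio - th.cnv_law[3]) <
                       abs(ratio - th.cnv_law[4]) else HOMOZYGOUS)
            calls.append(CnvCall(str(chrom), int(pm[idx[0]]), int(pm[idx[-1]]) + 1,
                                 direction, zyg, n, seg_t))
    return calls


# ---------------------------------------------------------------------------
# CSS design and gene conversions

@dataclass(frozen=True)
class CssDesign:
    """Which chromosome carries the donor genome, and who is host.

    ``host_state`` is the haplotype-map state of the host founder (F1 if
    the host is founder 1 of the genotype reference, F2 otherwise).
    """
    donor_chrom: str
    host_state: int = F1

    @property
    def donor_state(self) -> int:
        return F2 if self.host_state == F1 else F1

    @property
    def host_call(self) -> int:
        return CALL_A if self.host_state == F1 else CALL_B

    @property
    def donor_call(self) -> int:
        return CALL_B if self.host_state == F1 else CALL_A


@dataclass
class ConversionParams:
    max_run_markers: int = 2   # longer host runs are left to block classification
    flank_support: int = 5     # donor calls required on each side
    flank_window: int = 7      # nearest markers examined per side
    call_radius: float = 3.0


@dataclass(frozen=True)
class GeneConversionCall:
    chrom: str
    positions: tuple[int, ...]   # bp of the converted marker(s)
    probe_ids: tuple[str, ...]
    run_length: int
    flank_donor_left: int
    flank_donor_right: int
    host_distance: float         # intensity distance to host cluster (dispersions)
    donor_distance: float


def detect_gene_conversions(hmap: HaplotypeMap, callset: GenotypeCallSet,
                            intensities: IntensityTable, ref: FounderReference,
                            design: CssDesign,
                            params: ConversionParams | None = None,
                            ) -> list[GeneConversionCall]:
    """Find short host-genotype runs inside donor blocks of the donor chromosome.

    Candidate runs of at most ``max_run_markers`` host calls must be
    flanked on each side by at least ``flank_support`` donor calls among
    the nearest ``flank_window`` markers (with no host call among them),
    and the run's intensities must lie within ``call_radius`` dispersions
    of the host cluster (confident host, not merely N).
    """
    if design is None:
        raise ValueError("gene-conversion detection requires a CSS design")
    p = params or ConversionParams()
    chrom = design.donor_chrom
    if chrom not in hmap.positions:
        return []
    sample = hmap.sample
    pos, calls = callset.chrom_calls(sample, chrom)
    states = hmap.states[chrom]
    probe_ids = callset.probes.loc[callset.chrom_mask(chrom), "probe_id"].to_numpy()
    host_call, donor_call = design.host_call, design.donor_call

    info = ref.informative
    c_host = (ref.centers1 if design.host_state == F1 else ref.centers2)[info]
    c_donor = (ref.centers2 if design.host_state == F1 else ref.centers1)[info]
    disp_all = ref.dispersion[info]
    cmask = callset.chrom_mask(chrom)
    c_host, c_donor, disp = c_host[cmask], c_donor[cmask], disp_all[cmask]
    sig = intensities.select_class("snp").select_probes(info).signal(sample)[cmask]

    in_donor_block = states == design.donor_state
    is_host = (calls == host_call) & in_donor_block
    out: list[GeneConversionCall] = []
    i = 0
    n = len(calls)
    while i < n:
        if not is_host[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and is_host[j + 1]:
            j += 1
        run = np.arange(i, j + 1)
        i = j + 1
        if len(run) > p.max_run_markers:
            continue
        left = calls[max(0, run[0] - p.flank_window):run[0]]
        right = calls[run[-1] + 1:run[-1] + 1 + p.flank_window]
        ld, rd = int((left == donor_call).sum()), int((right == donor_call).sum())
        if ld < p.flank_support or rd < p.flank_support:
            continue
        if (left == host_call).any() or (right == host_call).any():
            continue
        dh = np.hypot(sig[run, 0] - c_host[run, 0], sig[run, 1] - c_host[run, 1])
        dd = np.hypot(sig[run, 0] - c_donor[run, 0], sig[run, 1] - c_donor[run, 1])
        rel_h = dh / disp[run]
        if np.any(rel_h > p.call_radius):
            continue
        out.append(GeneConversionCall(chrom, tuple(int(x) for x in pos[run]),
                                      tuple(str(s) for s in probe_ids[run]),
                                      len(run), ld, rd,
                                      float(rel_h.mean()),
                                      float((dd / disp[run]).mean())))
    return out


# ---------------------------------------------------------------------------
# unexpected haplotype blocks

END_PASSENGER = "end_passenger"
INTERNAL_DONOR_GAP = "internal_donor_gap"
OFF_CHROMOSOME_DONOR = "off_chromosome_donor"
HET_RESIDUAL = "het_residual"


@dataclass(frozen=True)
class UnexpectedBlock:
    strain: str
    chrom: str
    start_bp: int   # bp of the block's first marker
    end_bp: int     # half-open: last marker position + 1
    expected: int   # state expected from the design
    observed: int
    blk_class: str
    n_markers: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


def classify_unexpected_blocks(hmap: HaplotypeMap, design: CssDesign,
                               ) -> list[UnexpectedBlock]:
    """Report every block whose state contradicts the CSS design.

    On the donor chromosome host blocks touching an end are passenger
    segments beyond the outermost selection markers (``end_passenger``);
    host blocks strictly inside are ``internal_donor_gap``.  Donor blocks
    on background chromosomes are ``off_chromosome_donor``.  Het blocks
    anywhere are residual heterozygosity (``het_residual``).
    """
    out: list[UnexpectedBlock] = []
    for chrom in hmap.chromosomes:
        expected = design.donor_state if chrom == design.donor_chrom else design.host_state
        blocks = hmap.blocks(chrom)
        n_blocks = len(blocks)
        for k, b in enumerate(blocks):
            if b.state == expected:
                continue
            if b.state == HET:
                cls = HET_RESIDUAL
            elif chrom == design.donor_chrom:
                cls = END_PASSENGER if k in (0, n_blocks - 1) else INTERNAL_DONOR_GAP
            else:
                cls = OFF_CHROMOSOME_DONOR
            out.append(UnexpectedBlock(hmap.sample, chrom, b.start_bp, b.end_bp + 1,
                                       expected, b.state, cls, b.n_markers))
    return out
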