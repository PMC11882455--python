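"""Analysis thresholds and physical constants, collected in one place.

All length thresholds that the classifiers and detectors use live here so
that every module converts pixels to micrometres the same way and no
threshold is inlined at a call site.
"""

# --- image calibration -----------------------------------------------------
#: default pixel pitch of the low-magnification network scans (μm / px)
PIXEL_SIZE_UM = 3.25

# --- edge classification (BAS vs runner hyphae) ----------------------------
#: criterion 1: edges shorter than this are branched absorbing structures
BAS_MAX_LENGTH_UM = 400.0
#: criterion 2: edges shorter than this with a tip endpoint are BAS
BAS_TIP_MAX_LENGTH_UM = 1000.0
#: criterion 3a: average width below this ...
BAS_MAX_WIDTH_UM = 7.0
#: criterion 3b: ... combined with width*length below this, is BAS
BAS_MAX_WIDTH_LENGTH_UM2 = 9000.0

# --- tip tracking ----------------------------------------------------------
#: a degree-1 node must move at least this many pixels between frames to
#: count as a growing tip
GROWING_TIP_MIN_DISPLACEMENT_PX = 40
#: growing tips whose net displacement exceeds this are runner-hypha tips
RH_TIP_NET_DISPLACEMENT_UM = 2500.0

# --- ring frame ------------------------------------------------------------
#: number of equal-area concentric half-annuli used for density profiles
N_RINGS = 15
#: cells per ring for the bootstrap uncertainty of ring densities
BOOTSTRAP_N_CELLS = 10000
#: bootstrap resamples for ring-density uncertainties
BOOTSTRAP_N_RESAMPLES = 100
#: bootstrap resamples for sigmoid-fit confidence intervals
SIGMOID_BOOTSTRAP_N = 1000

# --- region of interest ----------------------------------------------------
#: offset of the analysis region from the compartment barrier (mm)
ROI_BARRIER_OFFSET_MM = 6.0
#: radius of the semicircular analysis region (mm)
ROI_RADIUS_MM = 45.0

# --- kymograph flow analysis -----------------------------------------------
#: minimum trajectory duration, in consecutive frames
TRAJECTORY_MIN_FRAMES = 10
#: spatial extent of the line region of interest (μm)
KYMOGRAPH_ROI_LENGTH_UM = 20.0
#: immotile-object speed threshold (μm/s); see also immotile_threshold_um_s
IMMOTILE_SPEED_UM_S = 0.8
#: maximum acceptable video-to-network alignment error (μm)
FLOW_ALIGNMENT_TOLERANCE_UM = 100.0

#: Boltzmann constant (J/K), water viscosity (Pa s) and particle radius (m)
#: used to recompute the immotile threshold from first principles
BOLTZMANN_J_PER_K = 1.380649e-23
WATER_VISCOSITY_PA_S = 0.89e-3
TRACKED_PARTICLE_RADIUS_M = 35e-9
ROOM_TEMPERATURE_K = 298.0
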