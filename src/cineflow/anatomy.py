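"""Vessel label vocabulary and compartment membership for the two planes.

The extracranial plane (C2-C3 cervical level) carries the four feeding
arteries (internal carotids, vertebrals) and the cervical venous return
(internal jugular, epidural, and small posterior veins).  The intracranial
plane carries the carotid siphons and basilar artery plus the two large dural
sinuses (straight and superior sagittal).

Compartment flows are simple sums of their members' flow curves:
ExtraArt / ExtraVein at the cervical plane, IntraArt / IntraVein at the
intracranial plane.  Venous drainage dominance is judged for the "main"
pathway of each plane -- the internal jugular veins extracranially, the two
sinuses intracranially -- as a fraction of the arterial compartment mean.
"""

from __future__ import annotations

RIGHT_ICA = "right_internal_carotid"
LEFT_ICA = "left_internal_carotid"
RIGHT_VA = "right_vertebral"
LEFT_VA = "left_vertebral"
RIGHT_IJV = "right_internal_jugular"
LEFT_IJV = "left_internal_jugular"
RIGHT_EV = "right_epidural"
LEFT_EV = "left_epidural"
POSTERIOR = "posterior_veins"
BASILAR = "basilar_artery"
STRAIGHT_SINUS = "straight_sinus"
SSS = "superior_sagittal_sinus"

EXTRA_ART_MEMBERS = (RIGHT_ICA, LEFT_ICA, RIGHT_VA, LEFT_VA)
EXTRA_VEIN_MEMBERS = (RIGHT_IJV, LEFT_IJV, RIGHT_EV, LEFT_EV, POSTERIOR)
INTRA_ART_MEMBERS = (RIGHT_ICA, LEFT_ICA, BASILAR)
INTRA_VEIN_MEMBERS = (STRAIGHT_SINUS, SSS)

#: name -> (arterial compartment, venous compartment) member tuples per plane
COMPARTMENTS = {
    "extracranial": {
        "ExtraArt": EXTRA_ART_MEMBERS,
        "ExtraVein": EXTRA_VEIN_MEMBERS,
    },
    "intracranial": {
        "IntraArt": INTRA_ART_MEMBERS,
        "IntraVein": INTRA_VEIN_MEMBERS,
    },
}

#: the venous pathway whose share decides drainage dominance, per plane
DOMINANCE_PATHWAY = {
    "extracranial": (RIGHT_IJV, LEFT_IJV),
    "intracranial": (STRAIGHT_SINUS, SSS),
}

PLANE_VESSELS = {
    "extracranial": EXTRA_ART_MEMBERS + EXTRA_VEIN_MEMBERS,
    "intracranial": INTRA_ART_MEMBERS + INTRA_VEIN_MEMBERS,
}
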