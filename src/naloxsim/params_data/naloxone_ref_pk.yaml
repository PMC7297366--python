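# Naloxone plasma PK: first-order IM absorption into a linear
# two-compartment disposition model, after the published population model
# for IV/IM/IN naloxone in volunteers.  Values below are representative of
# that model (70-kg adult) and of product-label IM naloxone PK (Cmax a few
# ng/ml for 2 mg IM, Tmax 10-20 min); every entry is config-overridable.
model: first_order_absorption_two_compartment
CL_L_per_h: 91.0        # systemic clearance
V1_L: 26.9              # central volume
Q_L_per_h: 110.0        # intercompartmental clearance
V2_L: 59.2              # peripheral volume
F_IM: 0.36              # absolute IM bioavailability
ka_per_min: 0.15        # IM absorption rate (t1/2,abs ~ 4.6 min)
in_to_im_factor: 0.45   # IN relative bioavailability vs IM
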