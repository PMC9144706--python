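sample_id,area,location,hi,ir_commercial,ir_institutional
R01,Wastewater treatment,Wastewater collection tank,0.227,1.78e-5,3.22e-6
R02,Wastewater treatment,Wastewater collection tank,0.152,9.38e-6,1.70e-6
R03,Wastewater treatment,Oil-water separation tank,0.174,1.17e-5,2.11e-6
R04,Wastewater treatment,Flocculation tank,0.383,2.52e-5,4.57e-6
R05,Wastewater treatment,Flocculation tank,0.149,1.01e-5,1.83e-6
R06,Wastewater treatment,Flotation tank,0.418,2.80e-5,5.07e-6
R07,Wastewater treatment,Flotation tank,0.164,1.07e-5,1.94e-6
R08,Wastewater treatment,Oily sludge tank,0.287,1.84e-5,3.33e-6
R09,Wastewater treatment,Activated-sludge treatment tank,0.794,5.00e-5,9.05e-6
R10,Wastewater treatment,Activated-sludge treatment tank,0.349,2.49e-5,4.51e-6
R11,Wastewater treatment,Sedimentation tank,0.290,2.01e-5,3.64e-6
R12,Wastewater treatment,Sedimentation tank,0.618,4.52e-5,8.18e-6
R13,Wastewater treatment,Sludge thickener tank,0.382,2.77e-5,5.01e-6
R14,Wastewater treatment,Final collection,0.484,3.51e-5,6.35e-6
R15,Vapour recovery unit system,Vapour recovery unit outlet,0.325,2.22e-5,4.02e-6
R16,Vapour recovery unit system,Vapour recovery unit outlet,0.278,1.32e-5,2.39e-6
R17,Vapour recovery unit system,Vapour recovery unit outlet,0.258,1.62e-5,2.94e-6
R18,Tanks,Fuel oil tank,0.128,7.51e-6,1.36e-6
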