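# SYNTHETIC effective cross-sectional areas (mm^2) per articulating section.
# Anatomically plausible endplate areas increasing cervical -> lumbar; cortical
# shell taken as 20% of the vertebral area, cancellous core the remainder; disc
# area is the mean of the adjacent vertebral areas, split 60% annulus / 40% nucleus.
# These values are not measured data; they shape only the relative stress profile
# (the absolute demand level is set by calibration) and are fully user-replaceable.
section,vertebra_area_mm2,cortical_area_mm2,cancellous_area_mm2,disc_area_mm2,annulus_area_mm2,nucleus_area_mm2
C1,200,40.0,160.0,205.0,123.0,82.0
C2,210,42.0,168.0,215.0,129.0,86.0
C3,220,44.0,176.0,225.0,135.0,90.0
C4,230,46.0,184.0,235.0,141.0,94.0
C5,240,48.0,192.0,245.0,147.0,98.0
C6,250,50.0,200.0,255.0,153.0,102.0
C7,260,52.0,208.0,280.0,168.0,112.0
T1,300,60.0,240.0,320.0,192.0,128.0
T2,340,68.0,272.0,360.0,216.0,144.0
T3,380,76.0,304.0,400.0,240.0,160.0
T4,420,84.0,336.0,440.0,264.0,176.0
T5,460,92.0,368.0,480.0,288.0,192.0
T6,500,100.0,400.0,520.0,312.0,208.0
T7,540,108.0,432.0,560.0,336.0,224.0
T8,580,116.0,464.0,600.0,360.0,240.0
T9,620,124.0,496.0,640.0,384.0,256.0
T10,660,132.0,528.0,680.0,408.0,272.0
T11,700,140.0,560.0,720.0,432.0,288.0
T12,740,148.0,592.0,770.0,462.0,308.0
L1,800,160.0,640.0,825.0,495.0,330.0
L2,850,170.0,680.0,875.0,525.0,350.0
L3,900,180.0,720.0,925.0,555.0,370.0
L4,950,190.0,760.0,975.0,585.0,390.0
L5,1000,200.0,800.0,,,
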