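wavelength_nm,eps_hbo2_cm_M,eps_hhb_cm_M
500,21000.0,21500.0
502,22056.9,22010.5
504,23146.6,22631.6
506,24267.8,23347.4
508,25419.4,24142.1
510,26600.0,25000.0
512,27759.9,25916.6
514,28902.0,26928.8
516,30104.2,28082.6
518,31444.3,29424.3
520,33000.0,31000.0
522,35145.0,33628.5
524,37872.3,37345.9
526,40688.4,41024.1
528,43100.0,43534.9
530,44700.4,44111.7
532,45817.2,44251.1
534,46813.6,44351.3
536,48000.0,44500.0
538,49963.6,44702.7
540,52159.6,44993.0
542,53200.0,45500.0
544,51361.8,48634.5
546,48729.7,50524.6
548,45897.3,51216.2
550,43000.0,51800.0
552,39826.7,52607.2
554,36902.2,53287.8
556,35393.8,53353.4
558,34405.3,53028.4
560,34000.0,52500.0
562,34947.2,51287.0
564,36969.6,49411.1
566,39052.8,47620.4
568,41513.7,45764.5
570,44000.0,44000.0
572,46474.2,42488.0
574,48500.0,41000.0
576,49843.3,38972.3
578,49605.6,38759.3
580,47000.0,39500.0
582,43017.6,39002.2
584,38000.0,38000.0
586,32815.6,36747.0
588,27311.5,35055.6
590,22000.0,33000.0
592,16793.3,30251.9
594,11955.6,26807.7
596,8316.1,23142.5
598,5365.0,19109.9
600,3200.0,14700.0
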