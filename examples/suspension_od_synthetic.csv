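wavelength_nm,od
400,0.08
405,0.08
410,0.08
415,0.08
420,0.08
425,0.08
430,0.08
435,0.08
440,0.08
445,0.08
450,0.08
455,0.08
460,0.08
465,0.08
470,0.08
475,0.08
480,0.08
485,0.08
490,0.08
495,0.08
500,0.08
505,0.08001
510,0.08003
515,0.08007
520,0.08015
525,0.08033
530,0.08069
535,0.08139
540,0.08269
545,0.085
550,0.08893
555,0.09532
560,0.10526
565,0.12001
570,0.1409
575,0.16905
580,0.20512
585,0.24889
590,0.29904
595,0.35294
600,0.40677
605,0.4559
610,0.4955
615,0.52145
620,0.53116
625,0.52442
630,0.50397
635,0.47559
640,0.44737
645,0.42774
650,0.42237
655,0.43085
660,0.44534
665,0.45284
670,0.4409
675,0.4038
680,0.34548
685,0.27728
690,0.21226
695,0.1598
700,0.12329
705,0.10111
710,0.08926
715,0.08366
720,0.08131
725,0.08043
730,0.08013
735,0.08004
740,0.08001
745,0.08
750,0.08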