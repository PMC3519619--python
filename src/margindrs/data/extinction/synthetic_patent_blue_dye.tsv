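# wavelength_nm	epsilon
450.0	4.46075967e-03
451.0	4.54168245e-03
452.0	4.62130249e-03
453.0	4.69949723e-03
454.0	4.77614481e-03
455.0	4.85112443e-03
456.0	4.92431666e-03
457.0	4.99560383e-03
458.0	5.06487035e-03
459.0	5.13200308e-03
460.0	5.19689171e-03
461.0	5.25942906e-03
462.0	5.31951152e-03
463.0	5.37703934e-03
464.0	5.43191699e-03
465.0	5.48405357e-03
466.0	5.53336308e-03
467.0	5.57976482e-03
468.0	5.62318372e-03
469.0	5.66355065e-03
470.0	5.70080277e-03
471.0	5.73488386e-03
472.0	5.76574461e-03
473.0	5.79334296e-03
474.0	5.81764438e-03
475.0	5.83862219e-03
476.0	5.85625783e-03
477.0	5.87054115e-03
478.0	5.88147074e-03
479.0	5.88905412e-03
480.0	5.89330808e-03
481.0	5.89425894e-03
482.0	5.89194279e-03
483.0	5.88640579e-03
484.0	5.87770443e-03
485.0	5.86590578e-03
486.0	5.85108780e-03
487.0	5.83333958e-03
488.0	5.81276166e-03
489.0	5.78946629e-03
490.0	5.76357777e-03
491.0	5.73523273e-03
492.0	5.70458050e-03
493.0	5.67178341e-03
494.0	5.63701719e-03
495.0	5.60047135e-03
496.0	5.56234959e-03
497.0	5.52287019e-03
498.0	5.48226654e-03
499.0	5.44078758e-03
500.0	5.39869831e-03
501.0	5.35628038e-03
502.0	5.31383264e-03
503.0	5.27167174e-03
504.0	5.23013284e-03
505.0	5.18957024e-03
506.0	5.15035815e-03
507.0	5.11289143e-03
508.0	5.07758637e-03
509.0	5.04488159e-03
510.0	5.01523885e-03
511.0	4.98914400e-03
512.0	4.96710791e-03
513.0	4.94966743e-03
514.0	4.93738643e-03
515.0	4.93085678e-03
516.0	4.93069946e-03
517.0	4.93756557e-03
518.0	4.95213743e-03
519.0	4.97512969e-03
520.0	5.00729040e-03
521.0	5.04940208e-03
522.0	5.10228280e-03
523.0	5.16678724e-03
524.0	5.24380767e-03
525.0	5.33427497e-03
526.0	5.43915951e-03
527.0	5.55947204e-03
528.0	5.69626447e-03
529.0	5.85063057e-03
530.0	6.02370657e-03
531.0	6.21667169e-03
532.0	6.43074844e-03
533.0	6.66720294e-03
534.0	6.92734492e-03
535.0	7.21252766e-03
536.0	7.52414772e-03
537.0	7.86364445e-03
538.0	8.23249931e-03
539.0	8.63223496e-03
540.0	9.06441409e-03
541.0	9.53063800e-03
542.0	1.00325449e-02
543.0	1.05718080e-02
544.0	1.11501331e-02
545.0	1.17692560e-02
546.0	1.24309399e-02
547.0	1.31369717e-02
548.0	1.38891585e-02
549.0	1.46893240e-02
550.0	1.55393039e-02
551.0	1.64409412e-02
552.0	1.73960812e-02
553.0	1.84065662e-02
554.0	1.94742297e-02
555.0	2.06008902e-02
556.0	2.17883446e-02
557.0	2.30383617e-02
558.0	2.43526748e-02
559.0	2.57329739e-02
560.0	2.71808984e-02
561.0	2.86980288e-02
562.0	3.02858781e-02
563.0	3.19458833e-02
564.0	3.36793966e-02
565.0	3.54876763e-02
566.0	3.73718776e-02
567.0	3.93330430e-02
568.0	4.13720935e-02
569.0	4.34898183e-02
570.0	4.56868661e-02
571.0	4.79637350e-02
572.0	5.03207639e-02
573.0	5.27581223e-02
574.0	5.52758024e-02
575.0	5.78736093e-02
576.0	6.05511534e-02
577.0	6.33078417e-02
578.0	6.61428702e-02
579.0	6.90552169e-02
580.0	7.20436348e-02
581.0	7.51066458e-02
582.0	7.82425354e-02
583.0	8.14493477e-02
584.0	8.47248811e-02
585.0	8.80666856e-02
586.0	9.14720597e-02
587.0	9.49380492e-02
588.0	9.84614466e-02
589.0	1.02038791e-01
590.0	1.05666370e-01
591.0	1.09340223e-01
592.0	1.13056140e-01
593.0	1.16809673e-01
594.0	1.20596137e-01
595.0	1.24410618e-01
596.0	1.28247981e-01
597.0	1.32102877e-01
598.0	1.35969758e-01
599.0	1.39842882e-01
600.0	1.43716331e-01
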