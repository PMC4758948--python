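{"comment": "Synthetic placeholder extinction bases for testing the pipeline; real analyses must supply literature molar extinction spectra.", "pigments": [{"name": "chlorophyll_a", "molecules_per_cell": 29400000.0, "wavelength_nm": [400, 405, 410, 415, 420, 425, 430, 435, 440, 445, 450, 455, 460, 465, 470, 475, 480, 485, 490, 495, 500, 505, 510, 515, 520, 525, 530, 535, 540, 545, 550, 555, 560, 565, 570, 575, 580, 585, 590, 595, 600, 605, 610, 615, 620, 625, 630, 635, 640, 645, 650, 655, 660, 665, 670, 675, 680, 685, 690, 695, 700, 705, 710, 715, 720, 725, 730, 735, 740, 745, 750], "extinction_M_cm": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.3, 0.8, 1.9, 4.4, 10.1, 22.0, 46.0, 92.7, 179.3, 333.3, 595.2, 1021.4, 1684.0, 2667.6, 4060.1, 5937.0, 8341.1, 11259.3, 14602.6, 18195.9, 21784.5, 25058.1, 27693.5, 29406.0, 30000.0, 29406.0, 27693.5, 25058.1, 21784.5, 18195.9, 14602.6, 11259.3, 8341.1, 5937.0, 4060.1, 2667.6, 1684.0, 1021.4, 595.2, 333.3, 179.3, 92.7, 46.0, 22.0, 10.1, 4.4, 1.9, 0.8, 0.3, 0.1, 0.0]}, {"name": "phycocyanobilin", "molecules_per_cell": 37000000.0, "wavelength_nm": [400, 405, 410, 415, 420, 425, 430, 435, 440, 445, 450, 455, 460, 465, 470, 475, 480, 485, 490, 495, 500, 505, 510, 515, 520, 525, 530, 535, 540, 545, 550, 555, 560, 565, 570, 575, 580, 585, 590, 595, 600, 605, 610, 615, 620, 625, 630, 635, 640, 645, 650, 655, 660, 665, 670, 675, 680, 685, 690, 695, 700, 705, 710, 715, 720, 725, 730, 735, 740, 745, 750], "extinction_M_cm": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1, 0.4, 1.7, 6.7, 24.1, 77.3, 222.2, 571.3, 1314.6, 2706.7, 4987.0, 8222.2, 12130.6, 16014.7, 18919.2, 20000.0, 18919.2, 16014.7, 12130.6, 8222.2, 4987.0, 2706.7, 1314.6, 571.3, 222.2, 77.3, 24.1, 6.7, 1.7, 0.4, 0.1, 0.0]}]}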